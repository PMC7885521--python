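"""Chromosome tables.

A :class:`GenomeTable` is the minimal genome description the pipeline needs:
an ordered list of (chromosome, length) pairs plus an *effective* genome
size, the mappable fraction of the genome used when converting total read
counts into the genome-wide expected background density ``lambda_BG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosome sizes plus an effective genome size.

    Parameters
    ----------
    chroms
        Tuple of ``(name, length_bp)`` pairs in the order windows and
        output files should follow. Names must be unique, lengths > 0.
    effective_genome_size
        Mappable genome size in bp used for ``lambda_BG``. Defaults to the
        sum of chromosome lengths, which is appropriate for fully mappable
        synthetic genomes; for human data pass e.g. ``2.7e9``.
    """

    chroms: tuple[tuple[str, int], ...]
    effective_genome_size: int = field(default=0)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has nonpositive length {length}")
        if self.effective_genome_size == 0:
            object.__setattr__(
                self, "effective_genome_size", sum(l for _, l in self.chroms)
            )
        if self.effective_genome_size <= 0:
            raise ValueError("effective genome size must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int], effective_genome_size: int = 0) -> "GenomeTable":
        return cls(tuple(sizes.items()), effective_genome_size)

    @classmethod
    def from_file(cls, path, effective_genome_size: int = 0) -> "GenomeTable":
        """Read a UCSC chrom.sizes style two-column text file."""
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom\\tlength'")
                try:
                    length = int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
                pairs.append((parts[0], length))
        return cls(tuple(pairs), effective_genome_size)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chroms:
                fh.write(f"{name}\t{length}\n")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chroms)

    def length(self, chrom: str) -> int:
        for name, l in self.chroms:
            if name == chrom:
                return l
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.chroms)
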