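"""Nonnegative mixture model of ChIP-seq background.

The treatment sample's windowed, depth-normalized read counts ``y_i`` are
modelled as a nonnegative linear combination of the controls' normalized
counts ``x_i`` plus a nonnegative offset:

    min_{theta, theta0}  (1/2n) * sum_i (y_i - theta . x_i - theta0)^2
    subject to           theta >= 0,  theta0 >= 0

The fitted weights make the combined control a per-treatment "smart"
background: controls irrelevant to this treatment's bias receive weight
exactly zero (active constraints of the NNLS solution, not thresholded
small values). With a single control and no fitting requested, the weight
defaults to exactly 1, which reproduces the classical unweighted
single-control pipeline bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .reads import MappedReadSet
from .windows import WindowCountMatrix, build_count_matrix, make_grid

log = logging.getLogger(__name__)


class ControlWeightModel:
    """NNLS regression of a treatment's windowed counts on its controls.

    Parameters
    ----------
    counts
        Window count matrix with the treatment as the last row.
    drop_all_zero
        If True, windows where every sample (controls and treatment) has
        zero reads are dropped before the regression. Such windows only
        shrink the offset toward zero; the default keeps them.
    subsample, seed
        Optional uniform subsample of windows (performance escape hatch,
        off by default — the regression normally uses every window).
    """

    def __init__(self, counts: WindowCountMatrix, drop_all_zero: bool = False,
                 subsample: int | None = None, seed: int = 0):
        self.counts = counts
        norm = counts.normalized
        X = norm[:-1].T            # (n_windows, k)
        y = norm[-1]
        if drop_all_zero:
            keep = (counts.raw_counts.sum(axis=0) > 0)
            X, y = X[keep], y[keep]
        if subsample is not None and subsample < len(y):
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(len(y), size=subsample, replace=False))
            X, y = X[idx], y[idx]
        if not np.any(y > 0):
            raise ValueError("treatment has no reads in any window")
        if len(y) < X.shape[1] + 1:
            raise ValueError(
                f"{len(y)} windows is too few to fit {X.shape[1]} controls")
        self.exog = X
        self.endog = y

    @classmethod
    def from_samples(cls, controls: list[MappedReadSet], treatment: MappedReadSet,
                     window_size: int = 200, step: int = 50, **kwargs
                     ) -> "ControlWeightModel":
        grid = make_grid(treatment.genome, window_size, step)
        return cls(build_count_matrix(controls, treatment, grid), **kwargs)

    def objective(self, theta: np.ndarray, theta0: float) -> float:
        resid = self.endog - self.exog @ np.asarray(theta, float) - theta0
        return float(0.5 * np.mean(resid ** 2))

    def fit(self) -> "ControlWeightResults":
        """Solve the NNLS problem; the offset is handled by augmenting the
        design with a constant-1 column so it obeys the same constraint."""
        n, k = self.exog.shape
        A = np.column_stack([self.exog, np.ones(n)])
        coef, _ = scipy.optimize.nnls(A, self.endog)
        theta, theta0 = coef[:k], float(coef[k])
        return ControlWeightResults(
            theta=theta, theta0=theta0,
            objective_value=self.objective(theta, theta0),
            source="fitted", control_ids=list(self.counts.control_ids),
            model=self, bse=self._approx_bse(A, coef),
        )

    def _approx_bse(self, A: np.ndarray, coef: np.ndarray) -> np.ndarray:
        """Approximate standard errors from the unconstrained least-squares
        problem restricted to the active (nonzero) support.

        These ignore both the nonnegativity constraints and the residual
        autocorrelation induced by overlapping windows, so they are
        diagnostics, not exact inference.
        """
        resid = self.endog - A @ coef
        dof = max(len(self.endog) - int(np.sum(coef > 0)), 1)
        sigma2 = float(resid @ resid) / dof
        bse = np.full(len(coef), np.nan)
        support = np.flatnonzero(coef > 0)
        if len(support):
            As = A[:, support]
            try:
                cov = sigma2 * np.linalg.inv(As.T @ As)
                bse[support] = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                pass
        return bse[:-1]  # per-control; offset SE not reported


@dataclass
class ControlWeightResults:
    """Fitted (or user-supplied) nonnegative control weights.

    ``theta`` holds one weight per control, ``theta0`` the nonnegative
    offset; ``objective_value`` is the achieved (1/2n) sum of squared
    residuals when the weights were fitted.
    """

    theta: np.ndarray
    theta0: float
    objective_value: float | None
    source: str                      # "fitted" | "user" | "user-default"
    control_ids: list[str]
    model: ControlWeightModel | None = None
    bse: np.ndarray | None = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < 0) or self.theta0 < 0:
            raise ValueError("control weights and offset must be nonnegative")

    @classmethod
    def from_user(cls, theta, control_ids=None, theta0: float = 0.0,
                  source: str = "user") -> "ControlWeightResults":
        theta = np.asarray(theta, dtype=float)
        if control_ids is None:
            control_ids = [f"control{i + 1}" for i in range(len(theta))]
        return cls(theta, theta0, None, source, list(control_ids))

    @classmethod
    def default_single_control(cls, control_id: str = "control1") -> "ControlWeightResults":
        """The single-control default: a weight of exactly 1."""
        return cls(np.array([1.0]), 0.0, None, "user-default", [control_id])

    @property
    def k(self) -> int:
        return len(self.theta)

    @property
    def nonzero(self) -> np.ndarray:
        return self.theta > 0

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        if exog is None:
            if self.model is None:
                raise ValueError("no model attached; pass exog explicitly")
            exog = self.model.exog
        return exog @ self.theta + self.theta0

    def summary(self) -> str:
        lines = [
            "Nonnegative control-mixture background model",
            "=" * 60,
            f"source: {self.source}    controls: {self.k}    "
            f"nonzero weights: {int(self.nonzero.sum())}",
        ]
        if self.objective_value is not None:
            lines.append(f"objective (1/2n * SSR): {self.objective_value:.6g}")
        lines.append(f"offset theta0: {self.theta0:.6g}")
        lines.append("-" * 60)
        lines.append(f"{'control':<24}{'weight':>12}{'frac':>10}{'approx SE':>12}")
        total = self.theta.sum()
        for i, cid in enumerate(self.control_ids):
            frac = self.theta[i] / total if total > 0 else 0.0
            se = "" if self.bse is None or np.isnan(self.bse[i]) else f"{self.bse[i]:.3g}"
            lines.append(f"{cid:<24}{self.theta[i]:>12.6g}{frac:>10.3f}{se:>12}")
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- persistence: TSV weight report + JSON settings ----------------

    def to_frame(self) -> pd.DataFrame:
        total = self.theta.sum()
        return pd.DataFrame({
            "control_id": self.control_ids,
            "weight": self.theta,
            "fraction_of_total_weight": self.theta / total if total > 0 else 0.0,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "source": self.source,
                "theta0": self.theta0,
                "objective_value": self.objective_value,
                "weights": dict(zip(self.control_ids, self.theta.tolist())),
            }, fh, indent=2)

    @classmethod
    def from_tsv(cls, path) -> "ControlWeightResults":
        df = pd.read_csv(path, sep="\t")
        return cls.from_user(df["weight"].to_numpy(),
                             control_ids=df["control_id"].tolist())


def fit_weights(counts: WindowCountMatrix, **kwargs) -> ControlWeightResults:
    """Convenience wrapper: build the model and fit in one call."""
    return ControlWeightModel(counts, **kwargs).fit()
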