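"""The patient- and position-specific background mutation model.

An unpenalized logistic regression of mutation status on the selected
position-level features plus always-included sample-level covariates,
fitted on the balanced case-control sample.  Because cases and controls
are sampled at different rates, the fitted intercept is corrected by
``- ln(f1/f0)`` at prediction time, returning probabilities on the
genome-wide prior scale.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.special import expit

from .features import FeatureAssembler
from .io import RegionSet
from .sampling import Standardizer

logger = logging.getLogger("hotscan")


class BackgroundModel:
    """Fitted logistic background model for one variant class."""

    def __init__(
        self,
        coefficients: pd.Series,      # includes "intercept"
        standard_errors: pd.Series,
        offset_correction: float,     # -ln(f1/f0), added to the intercept
        variant_class: str,
        column_categories: dict[str, str],
        standardizer: Standardizer,
        dropped_columns: list[str] | None = None,
        manifest_hash: str = "",
    ):
        self.coefficients = coefficients
        self.standard_errors = standard_errors
        self.offset_correction = float(offset_correction)
        self.variant_class = variant_class
        self.column_categories = dict(column_categories)
        self.standardizer = standardizer
        self.dropped_columns = list(dropped_columns or [])
        self.manifest_hash = manifest_hash

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.coefficients.index if c != "intercept"]

    @property
    def zvalues(self) -> pd.Series:
        se = self.standard_errors.replace(0, np.nan)
        return self.coefficients / se

    @property
    def corrected_intercept(self) -> float:
        return float(self.coefficients["intercept"]) + self.offset_correction

    def linear_predictor(self, X: np.ndarray, column_names: list[str]) -> np.ndarray:
        """Corrected-scale linear predictor for raw (unstandardized) rows."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        Xs = np.array(self.standardizer.transform(X, column_names))
        beta = self.coefficients.reindex(column_names).to_numpy()
        if np.isnan(beta).any():
            missing = [
                c for c, b in zip(column_names, self.coefficients.reindex(column_names))
                if np.isnan(b)
            ]
            raise KeyError(f"columns unknown to model: {missing}")
        return self.corrected_intercept + Xs @ beta

    def predict(self, X, column_names: list[str]) -> np.ndarray:
        return expit(self.linear_predictor(X, column_names))

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1,
            "variant_class": self.variant_class,
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.standard_errors.to_dict(),
            "offset_correction": self.offset_correction,
            "column_categories": self.column_categories,
            "scales": self.standardizer.scales,
            "dropped_columns": self.dropped_columns,
            "manifest_hash": self.manifest_hash,
            "column_order": list(self.coefficients.index),
        }
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "BackgroundModel":
        with open(path, "rt") as fh:
            payload = json.load(fh)
        order = payload["column_order"]
        return cls(
            coefficients=pd.Series(payload["coefficients"]).reindex(order),
            standard_errors=pd.Series(payload["standard_errors"]).reindex(order),
            offset_correction=payload["offset_correction"],
            variant_class=payload["variant_class"],
            column_categories=payload["column_categories"],
            standardizer=Standardizer(payload["scales"]),
            dropped_columns=payload["dropped_columns"],
            manifest_hash=payload["manifest_hash"],
        )


def manifest_hash(column_names: list[str]) -> str:
    return hashlib.sha256("\n".join(column_names).encode()).hexdigest()[:16]


def _drop_degenerate(X: np.ndarray, names: list[str]):
    """Remove constant and aliased (rank-deficient) columns."""
    keep = list(range(X.shape[1]))
    dropped = []
    const = [j for j in keep if X[:, j].std() == 0]
    for j in const:
        dropped.append(names[j])
        logger.warning("dropping constant column %r", names[j])
    keep = [j for j in keep if j not in const]
    if keep:
        sub = X[:, keep]
        # QR with pivoting on the centered columns finds aliased ones
        q, r, piv = scipy.linalg.qr(
            sub - sub.mean(axis=0), mode="economic", pivoting=True
        )
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(sub.shape) * np.finfo(float).eps * 1e3
        rank = int((diag > tol).sum())
        if rank < len(keep):
            aliased = [keep[j] for j in piv[rank:]]
            for j in sorted(aliased):
                dropped.append(names[j])
                logger.warning("dropping aliased column %r", names[j])
            keep = [j for j in keep if j not in aliased]
    return keep, dropped


def fit_background(
    X,
    y,
    column_names: list[str],
    column_categories: list[str] | dict[str, str],
    sampling_fractions: tuple[float, float],
    standardizer: Standardizer | None = None,
    variant_class: str = "SNV",
) -> BackgroundModel:
    """Unpenalized maximum-likelihood logistic fit with intercept correction.

    ``X`` holds the already-standardized selected features plus sample-level
    covariates.  Separation triggers a ridge-stabilized fallback with a
    warning; aliased or constant columns are dropped with a warning.
    """
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if isinstance(column_categories, list):
        column_categories = dict(zip(column_names, column_categories))
    keep, dropped = _drop_degenerate(X, column_names)
    kept_names = [column_names[j] for j in keep]
    Xk = X[:, keep]
    design = sm.add_constant(Xk, has_constant="add")
    params = se = None
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.bse)) and np.max(np.abs(fit.params)) < 30:
            params, se = fit.params, fit.bse
    except Exception:
        params = None
    if params is None:
        logger.warning("separation or non-convergence; ridge-stabilized refit")
        params, se = _ridge_logistic(design, y, alpha=1e-4)
    f1, f0 = sampling_fractions
    offset = -float(np.log(f1 / f0))
    index = ["intercept"] + kept_names
    return BackgroundModel(
        coefficients=pd.Series(params, index=index),
        standard_errors=pd.Series(se, index=index),
        offset_correction=offset,
        variant_class=variant_class,
        column_categories={c: column_categories.get(c, "") for c in kept_names},
        standardizer=standardizer or Standardizer({}),
        dropped_columns=dropped,
        manifest_hash=manifest_hash(kept_names),
    )


def _ridge_logistic(design: np.ndarray, y: np.ndarray, alpha: float):
    """Newton iterations for an L2-stabilized logistic fit (intercept too)."""
    n, p = design.shape
    beta = np.zeros(p)
    for _ in range(100):
        eta = design @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (design.T * w) @ design / n + alpha * np.eye(p)
        g = design.T @ (mu - y) / n + alpha * beta
        step = np.linalg.solve(H, g)
        beta -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = design @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (design.T * w) @ design / n + alpha * np.eye(p)
    cov = np.linalg.inv(H) / n
    return beta, np.sqrt(np.diag(cov))


def zvalue_table(model: BackgroundModel) -> pd.DataFrame:
    """Feature Z-values (beta / SE), sorted by |Z| descending, ties by name."""
    z = model.zvalues.drop("intercept")
    df = pd.DataFrame({"feature": z.index, "zvalue": z.to_numpy()})
    df["absz"] = df["zvalue"].abs()
    df = df.sort_values(["absz", "feature"], ascending=[False, True], kind="stable")
    return df.drop(columns="absz").reset_index(drop=True)


class ProbabilityField:
    """(sample, position) -> background mutation probability.

    Factorizes as a cached per-position linear predictor plus a per-sample
    scalar; any evaluation order yields identical values.  Positions outside
    the analyzable mask raise; in-mask positions without a valid sequence
    context yield NaN (callers skip them in window products).
    """

    def __init__(
        self,
        model: BackgroundModel,
        assembler: FeatureAssembler,
        mask: RegionSet,
        block_size: int = 1_000_000,
    ):
        self.model = model
        self.assembler = assembler
        self.mask = mask
        self.block_size = block_size
        self._eta_cache: dict[str, np.ndarray] = {}
        cov = assembler.sample_covariates
        if cov is None:
            raise ValueError("assembler must carry sample covariates")
        self.samples = list(cov.samples)
        gam = model.coefficients.reindex(cov.column_names).fillna(0.0).to_numpy()
        Z = cov.design_columns(self.samples)
        self.sample_offsets = Z @ gam
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        beta_pos = model.coefficients.reindex(assembler.position_columns)
        self._beta_pos = beta_pos.fillna(0.0).to_numpy()
        self._pos_names = assembler.position_columns

    def _positional_eta(self, contig: str) -> np.ndarray:
        """Corrected intercept + position-feature contribution, NaN where
        the position is unavailable (masked out or no context)."""
        if contig in self._eta_cache:
            return self._eta_cache[contig]
        length = self.assembler.genome.lengths[contig]
        eta = np.full(length, np.nan)
        base = self.model.corrected_intercept
        for lo in range(0, length, self.block_size):
            hi = min(lo + self.block_size, length)
            pos = np.arange(lo, hi, dtype=np.int64)
            ok = self.mask.contains(contig, pos)
            ok &= self.assembler.context_available(contig, pos)
            if not ok.any():
                continue
            sel = pos[ok]
            X = self.assembler.position_matrix(contig, sel)
            X = self.model.standardizer.transform(X, self._pos_names)
            eta[sel] = base + X @ self._beta_pos
        self._eta_cache[contig] = eta
        return eta

    def window_success(
        self, contig: str, start: int, end: int
    ) -> np.ndarray:
        """Per-sample probability of >=1 mutation in [start, end).

        q_i = 1 - prod_j (1 - p_ij) over the window's available positions
        (masked or context-less positions contribute nothing).
        """
        eta = self._positional_eta(contig)[start:end]
        eta = eta[np.isfinite(eta)]
        if len(eta) == 0:
            return np.zeros(len(self.samples))
        # log(1-p) summed per sample, vectorized over (samples, positions)
        z = eta[None, :] + self.sample_offsets[:, None]
        log1mp = -np.logaddexp(0.0, z)
        return -np.expm1(log1mp.sum(axis=1))

    def probability(
        self, sample_id: str, contig: str, position0: int
    ) -> float:
        """Background probability for one 0-based position."""
        if sample_id not in self._sample_index:
            raise KeyError(f"unknown sample {sample_id!r}")
        if not self.mask.contains(contig, np.array([position0]))[0]:
            raise ValueError(f"{contig}:{position0} is outside the analyzable mask")
        eta = self._positional_eta(contig)[position0]
        if not np.isfinite(eta):
            raise ValueError(f"{contig}:{position0} has no valid sequence context")
        return float(expit(eta + self.sample_offsets[self._sample_index[sample_id]]))


def predict_probability(
    field: ProbabilityField, sample_id: str, contig: str, position: int
) -> float:
    """Probability at a 1-based position (convenience wrapper)."""
    return field.probability(sample_id, contig, position - 1)
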