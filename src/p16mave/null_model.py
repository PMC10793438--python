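"""Gamma-GLM null model for pooled variant-competition ratios.

The assay decides whether a variant confers a fitness advantage from the count
ratio ``r_cf`` between the tested variant and a reference (synonymous) variant
at confluency.  Under the null (both neutral), ``r_cf`` is modelled as

    r_cf ~ Gamma(shape=alpha, mean=mu_v),   mu_v = r_init^a * p_init^b,

where ``r_init`` is the same ratio at Day 9 and ``p_init`` the tested
variant's Day-9 proportion within its library.  This is a gamma GLM with log
link and covariates ``log r_init`` and ``log p_init`` (no intercept: the mean
formula has none), with a single shape ``alpha`` shared across variants.

Calibration uses all-neutral control pools (20 CellTag barcodes, 3
experiments): within each experiment every barcode serves in turn as the
reference and the remaining 19 contribute one triplet each — 19 x 20 = 380
triplets per experiment, 1,140 across the triplicate.

A variant's p-value is the upper-tail probability of its fitted null gamma at
the observed ``r_cf``; only a fitness *advantage* (increased ``r_cf``) is the
alternative — depletion is reported descriptively, not classified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "Triplet",
    "NullModel",
    "DegenerateInputError",
    "FitError",
    "build_triplets",
    "assay_triplets",
    "fit_null",
    "variant_pvalue",
    "variant_log_pvalue",
    "triplets_to_frame",
]

TRIPLET_COLUMNS = ["experiment", "reference", "variant", "r_cf", "r_init", "p_init"]


class DegenerateInputError(ValueError):
    """Zero or otherwise unusable counts with pseudocounting disabled."""


class FitError(RuntimeError):
    """The GLM fit did not converge or the inputs admit no fit."""


@dataclass(frozen=True)
class Triplet:
    """One (tested variant vs reference) observation: ratios at confluency and
    Day 9, plus the tested variant's Day-9 proportion in its library."""

    r_cf: float
    r_init: float
    p_init: float

    def __post_init__(self) -> None:
        for name in ("r_cf", "r_init", "p_init"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise DegenerateInputError(f"{name} must be positive and finite, got {v}")
        if self.p_init >= 1:
            raise DegenerateInputError(f"p_init must be < 1, got {self.p_init}")


@dataclass
class NullModel:
    """Calibrated null: shape ``alpha`` plus mean-model exponents ``a`` (on
    r_init) and ``b`` (on p_init), optionally a log-scale intercept."""

    shape: float
    exp_rinit: float
    exp_pinit: float
    intercept: float = 0.0
    log_likelihood: float = float("nan")
    n: int = 0
    converged: bool = True
    shape_method: str = "ml"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shape) and self.shape > 0):
            raise FitError(f"gamma shape must be positive, got {self.shape}")

    def predicted_mean(self, r_init, p_init):
        """mu_v = exp(intercept) * r_init^a * p_init^b (vectorised)."""
        r = np.asarray(r_init, dtype=float)
        p = np.asarray(p_init, dtype=float)
        return np.exp(self.intercept + self.exp_rinit * np.log(r) + self.exp_pinit * np.log(p))

    def to_json(self, path=None) -> str:
        doc = {
            "model": "gamma_glm_null",
            "shape": self.shape,
            "exp_rinit": self.exp_rinit,
            "exp_pinit": self.exp_pinit,
            "intercept": self.intercept,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "converged": self.converged,
            "shape_method": self.shape_method,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "NullModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        doc.pop("model", None)
        return cls(
            shape=doc["shape"],
            exp_rinit=doc["exp_rinit"],
            exp_pinit=doc["exp_pinit"],
            intercept=doc.get("intercept", 0.0),
            log_likelihood=doc.get("log_likelihood", float("nan")),
            n=doc.get("n", 0),
            converged=doc.get("converged", True),
            shape_method=doc.get("shape_method", "ml"),
        )


def _pseudocounted(values: np.ndarray, pseudocount: float | None) -> np.ndarray:
    if pseudocount is None:
        if (values <= 0).any():
            raise DegenerateInputError(
                "zero count encountered with pseudocounting disabled"
            )
        return values.astype(float)
    return values.astype(float) + pseudocount


def build_triplets(
    control_tables: Iterable[pd.DataFrame],
    pseudocount: float | None = 0.5,
) -> pd.DataFrame:
    """All-vs-all calibration triplets from all-neutral control experiments.

    Within each experiment every variant serves in turn as the reference and
    each remaining variant contributes one triplet against it, giving
    ``k * (k - 1)`` triplets per experiment of ``k`` barcodes.  Counts receive
    ``pseudocount`` (default +0.5) before ratios; pass ``None`` to instead
    raise :class:`DegenerateInputError` on zero counts.
    """
    rows = []
    for exp_idx, table in enumerate(control_tables, start=1):
        if len(table) < 2:
            raise DegenerateInputError("control experiment needs >= 2 variants")
        names = table["alt_aa"].to_numpy()
        c9 = _pseudocounted(table["count_day9"].to_numpy(), pseudocount)
        ccf = _pseudocounted(table["count_confluent"].to_numpy(), pseudocount)
        p_init = c9 / c9.sum()
        k = len(names)
        for ref in range(k):
            for v in range(k):
                if v == ref:
                    continue
                rows.append(
                    (
                        exp_idx,
                        names[ref],
                        names[v],
                        ccf[v] / ccf[ref],
                        c9[v] / c9[ref],
                        p_init[v],
                    )
                )
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


def assay_triplets(
    count_table: pd.DataFrame,
    pseudocount: float | None = 0.5,
) -> pd.DataFrame:
    """Per-variant triplets for assay libraries, anchored on the synonymous
    variant at each residue (one triplet per missense variant per replicate).

    Expects the canonical count-table schema; returns one row per
    (library_id, replicate_id, missense variant) with columns
    ``variant``/``residue_index`` plus ``r_cf``/``r_init``/``p_init``.
    """
    rows = []
    for (lib, rep), group in count_table.groupby(["library_id", "replicate_id"], sort=True):
        syn = group[group["alt_aa"] == group["ref_aa"]]
        if len(syn) != 1:
            raise DegenerateInputError(
                f"library {lib!r} replicate {rep!r}: expected exactly one synonymous anchor"
            )
        c9 = _pseudocounted(group["count_day9"].to_numpy(), pseudocount)
        ccf = _pseudocounted(group["count_confluent"].to_numpy(), pseudocount)
        p_init = c9 / c9.sum()
        syn_pos = int(np.flatnonzero((group["alt_aa"] == group["ref_aa"]).to_numpy())[0])
        res = group["residue_index"].iloc[0]
        ref_aa = group["ref_aa"].iloc[0]
        for i, alt in enumerate(group["alt_aa"].to_numpy()):
            if i == syn_pos:
                continue
            rows.append(
                (
                    lib,
                    rep,
                    int(res),
                    f"{ref_aa}{res}{alt}",
                    ccf[i] / ccf[syn_pos],
                    c9[i] / c9[syn_pos],
                    p_init[i],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["library_id", "replicate_id", "residue_index", "variant", "r_cf", "r_init", "p_init"],
    )


def triplets_to_frame(triplets: Sequence[Triplet] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(triplets, pd.DataFrame):
        return triplets
    return pd.DataFrame(
        [(t.r_cf, t.r_init, t.p_init) for t in triplets],
        columns=["r_cf", "r_init", "p_init"],
    )


def _gamma_loglik(alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(stats.gamma.logpdf(y, a=alpha, scale=mu / alpha)))


def _shape_ml(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximum-likelihood gamma shape given fitted means, via the digamma
    equation  log(alpha) - psi(alpha) = mean(y/mu - log(y/mu)) - 1."""
    ratio = y / mu
    s = float(np.mean(ratio - np.log(ratio))) - 1.0
    if s <= 0:  # numerically perfect fit; dispersion ~ 0
        return 1e12
    f = lambda a: math.log(a) - special.digamma(a) - s
    # log(a) - psi(a) decreases from +inf to 0; bracket the root.
    lo, hi = 1e-12, 1.0
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e15:
            return 1e15
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def _shape_moments(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments shape from Pearson residuals (1 / dispersion)."""
    resid = (y - mu) / mu
    dispersion = float(np.sum(resid**2)) / max(len(y) - n_params, 1)
    return 1.0 / dispersion


def fit_null(
    triplets: Sequence[Triplet] | pd.DataFrame,
    include_intercept: bool = False,
    shape_method: str = "ml",
    max_iter: int = 200,
    tol: float = 1e-12,
) -> NullModel:
    """Fit the gamma GLM null by IRLS, then estimate the shared shape.

    The exponents ``a`` and ``b`` are estimated by iteratively reweighted
    least squares for a gamma GLM with log link (for which the working
    weights are identically 1, so each step is an ordinary least-squares
    solve on the adjusted response ``eta + (y - mu)/mu``).  The shape is then
    estimated at the fitted means, by default by maximising the gamma
    log-likelihood (``shape_method="ml"``), with method-of-moments on Pearson
    residuals available as ``shape_method="moments"``.
    """
    frame = triplets_to_frame(triplets)
    if len(frame) < 10:
        raise FitError(f"need >= 10 triplets to calibrate, got {len(frame)}")
    y = frame["r_cf"].to_numpy(dtype=float)
    if (y <= 0).any():
        raise DegenerateInputError("non-positive response ratio")
    X_cols = [np.log(frame["r_init"].to_numpy(dtype=float)),
              np.log(frame["p_init"].to_numpy(dtype=float))]
    if include_intercept:
        X_cols.append(np.ones(len(frame)))
    X = np.column_stack(X_cols)

    # Collinearity guard: the two covariates must not be linearly dependent.
    if np.linalg.matrix_rank(X @ X.T if X.shape[0] < X.shape[1] else X.T @ X) < X.shape[1]:
        raise FitError("collinear covariates: the GLM exponents are not identifiable")

    # IRLS with log link; initialise from OLS on log(y).
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        new_beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        if np.max(np.abs(new_beta - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = new_beta
            converged = True
            break
        beta = new_beta
    if not converged:
        raise FitError(f"IRLS did not converge in {max_iter} iterations")

    mu = np.exp(X @ beta)
    n_params = X.shape[1]
    if shape_method == "ml":
        alpha = _shape_ml(y, mu)
    elif shape_method == "moments":
        alpha = _shape_moments(y, mu, n_params)
    else:
        raise ValueError(f"unknown shape_method {shape_method!r}")

    return NullModel(
        shape=alpha,
        exp_rinit=float(beta[0]),
        exp_pinit=float(beta[1]),
        intercept=float(beta[2]) if include_intercept else 0.0,
        log_likelihood=_gamma_loglik(alpha, y, mu),
        n=len(y),
        converged=converged,
        shape_method=shape_method,
    )


def variant_pvalue(triplet: Triplet, model: NullModel) -> float:
    """Upper-tail gamma probability of observing a confluency ratio at least
    as large as ``r_cf`` under the fitted null.  Lies in (0, 1]."""
    mu = float(model.predicted_mean(triplet.r_init, triplet.p_init))
    p = float(stats.gamma.sf(triplet.r_cf, a=model.shape, scale=mu / model.shape))
    return max(p, 5e-324)  # keep strictly positive; use the log form for tails


def _gamma_logsf(x: np.ndarray, shape: float, scale: np.ndarray) -> np.ndarray:
    """Gamma log-survival with an asymptotic fallback far in the upper tail,
    where the regularised incomplete gamma underflows to 0 and scipy's
    ``logsf`` returns -inf.  Uses Gamma(a, z)/Gamma(a) ~ z^{a-1} e^{-z} /
    Gamma(a) * (1 + (a-1)/z) for large z."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    scale = np.broadcast_to(np.asarray(scale, dtype=float), x.shape)
    out = stats.gamma.logsf(x, a=shape, scale=scale)
    bad = ~np.isfinite(out)
    if bad.any():
        z = x[bad] / scale[bad]
        out[bad] = (
            (shape - 1.0) * np.log(z)
            - z
            - special.gammaln(shape)
            + np.log1p(np.maximum(shape - 1.0, 0.0) / z)
        )
    return out


def variant_log_pvalue(triplet: Triplet, model: NullModel) -> float:
    """Natural log of :func:`variant_pvalue`, computed without underflow."""
    mu = float(model.predicted_mean(triplet.r_init, triplet.p_init))
    return float(_gamma_logsf(np.array([triplet.r_cf]), model.shape, mu / model.shape)[0])


def log_pvalues(frame: pd.DataFrame, model: NullModel) -> np.ndarray:
    """Vectorised natural-log upper-tail p-values for a triplet frame."""
    mu = model.predicted_mean(frame["r_init"].to_numpy(), frame["p_init"].to_numpy())
    return _gamma_logsf(
        frame["r_cf"].to_numpy(dtype=float), model.shape, mu / model.shape
    )
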