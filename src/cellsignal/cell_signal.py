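"""Cell signal analysis: non-negative count-likelihood decomposition of bulk
transcriptomes against single-cell-defined reference profiles.

Model
-----
Let y_g be the bulk count of gene g and l_g its length. Length-normalized
intensities z_g = y_g / l_g are rescaled so that sum(z) = sum(y) (for TPM-style
inputs l_g = 1 and z = y). The expected intensity is an additive mixture of
the reference profiles f_gc (each column summing to 1 over the fitted genes)
plus a flat intercept u_g = 1/G:

    mu_g = sum_c beta_c f_gc + beta_0 u_g,      beta >= 0.

Parameters maximize the gene-weighted Poisson log-likelihood

    L(beta) = sum_g w_g (z_g log mu_g - mu_g),

with w_g = 0.5 for housekeeping genes, 0 for excluded/dropped genes and 1
otherwise (a quasi-likelihood: z may be non-integer after length
normalization). Because mu is linear in beta and the Poisson log-likelihood is
concave in mu, L is concave, so the multiplicative (EM-style) updates used
here converge to the global maximum from the deterministic uniform start.

Reported contributions are beta normalized to sum 1; the normalized intercept
weight w_0 is the *unexplained fraction* — the share of the bulk signal not
attributable to any reference cell type. Goodness of fit is a deviance-based
pseudo-R-squared against the intercept-only null, clipped to [0, 1].

A brute-force simplex grid search over the normalized weights (with the scale
profiled out analytically) is provided as an independent reference maximizer
for small instances.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BulkSample
from .reference_builder import ReferenceProfileSet

logger = logging.getLogger("cellsignal")

DEFAULT_MAX_ITER = 10_000
DEFAULT_TOL = 1e-8
MIN_GENES_WARN = 50


@dataclass
class SignalFit:
    """Result of fitting one bulk sample against a reference."""

    sample_id: str
    contributions: pd.Series  # per cell type, >= 0; with intercept sums to 1
    intercept: float  # w_0, the unexplained fraction
    pseudo_r2: float
    n_iter: int
    converged: bool
    log_likelihood: float
    gene_set_hash: str
    stage: str = ""

    def __post_init__(self) -> None:
        total = float(self.contributions.sum()) + self.intercept
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"contributions + intercept must sum to 1, got {total}")
        if not (0.0 <= self.pseudo_r2 <= 1.0):
            raise ValueError("pseudo_r2 must lie in [0, 1]")

    @property
    def unexplained(self) -> float:
        return self.intercept


@dataclass
class SummaryScore:
    """Group-level sums of contributions: embryoness, foetalness, adultness.

    ``group_scores`` holds one entry per developmental group present in the
    reference plus ``unexplained`` = w_0; together they sum to 1. Embryoness
    is early_embryo plus gastrulation when that group is present (the
    full-reference convention), controllable via ``include_gastrulation``.
    """

    sample_id: str
    group_scores: dict[str, float]
    include_gastrulation: bool = True

    def __post_init__(self) -> None:
        total = sum(self.group_scores.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group scores + unexplained must sum to 1, got {total}")

    @property
    def unexplained(self) -> float:
        return self.group_scores["unexplained"]

    @property
    def embryoness(self) -> float:
        s = self.group_scores.get("early_embryo", 0.0)
        if self.include_gastrulation:
            s += self.group_scores.get("gastrulation", 0.0)
        return s

    @property
    def foetalness(self) -> float:
        return self.group_scores.get("foetal", 0.0)

    @property
    def adultness(self) -> float:
        return self.group_scores.get("adult", 0.0)


# ---------------------------------------------------------------------------
# instance assembly
# ---------------------------------------------------------------------------

def _assemble_instance(
    bulk: BulkSample,
    reference: ReferenceProfileSet,
    drop_genes: Sequence[str] | None,
    min_genes: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], str]:
    """Intersect bulk and reference genes, apply exclusions/drops and weights.

    Returns (z, F, w, gene_ids, hash): length-normalized intensities, the
    column-renormalized profile matrix, per-gene weights, the fitted gene
    list, and a hash recording the gene set and weights in force. Genes with
    weight zero (excluded or dropped) are removed outright — weight-zero and
    removal are the same instance by construction.
    """
    drop = set(drop_genes or [])
    unknown = drop - set(reference.gene_ids) - set(bulk.gene_ids)
    if unknown:
        warnings.warn(f"drop_genes not in gene universe: {sorted(unknown)}", stacklevel=3)
    shared = [g for g in reference.gene_ids if g in set(bulk.gene_ids)]
    if not shared:
        raise ValueError(
            f"sample {bulk.sample_id}: no gene overlap between bulk and reference"
        )
    keep = [
        g for g in shared if g not in reference.excluded_genes and g not in drop
    ]
    if not keep:
        raise ValueError(f"sample {bulk.sample_id}: all shared genes excluded")
    if len(keep) < min_genes:
        warnings.warn(
            f"sample {bulk.sample_id}: only {len(keep)} genes in the fit "
            f"(< {min_genes}); estimates may be unstable",
            stacklevel=3,
        )
    y = bulk.counts.reindex(keep).to_numpy(dtype=float)
    l = bulk.lengths.reindex(keep).to_numpy(dtype=float)
    z = y / l
    if z.sum() == 0:
        raise ValueError(f"sample {bulk.sample_id}: all fitted counts are zero")
    z = z * (y.sum() / z.sum())
    F = reference.profiles.reindex(keep).to_numpy(dtype=float)
    col_sums = F.sum(axis=0)
    if (col_sums == 0).any():
        bad = [c for c, s in zip(reference.cell_types, col_sums) if s == 0]
        raise ValueError(f"reference columns with zero mass on fitted genes: {bad}")
    F = F / col_sums
    w = reference.gene_weights.reindex(keep).to_numpy(dtype=float)
    h = hashlib.sha1(
        "\n".join(f"{g}\t{wt:.6g}" for g, wt in zip(keep, w)).encode()
    ).hexdigest()
    return z, F, w, keep, h


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def weighted_poisson_loglik(z: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """sum_g w_g (z_g log mu_g - mu_g), with the z log z constant omitted."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(z > 0, z * np.log(mu), 0.0)
    return float(np.sum(w * (term - mu)))


def weighted_poisson_deviance(z: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """Weighted Poisson deviance vs the saturated model (mu = z)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(z > 0, z * np.log(z / mu), 0.0)
    return float(2.0 * np.sum(w * (ratio - (z - mu))))


def _fit_mixture(
    z: np.ndarray,
    F: np.ndarray,
    w: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, int, bool]:
    """Maximize the weighted Poisson likelihood over beta >= 0.

    F already includes the intercept as its last column. Multiplicative
    updates (the EM update for additive Poisson components) increase the
    likelihood monotonically; uniform deterministic initialization.
    """
    G, K = F.shape
    beta = np.full(K, z.sum() / K)
    denom = F.T @ w  # sum_g w_g f_gk, constant across iterations
    wz = w * z
    ll = -np.inf
    alpha = beta / beta.sum()
    converged = False
    it = 0
    # stop only once the likelihood has plateaued AND the normalized weights
    # are stable: the likelihood alone flattens long before the weights settle
    # on sublinear EM tails, which would break scale invariance and oracle
    # agreement at the tolerances this method promises
    for it in range(1, max_iter + 1):
        mu = F @ beta
        beta = beta * (F.T @ (wz / mu)) / denom
        if it % 10 == 0 or it == max_iter:
            mu = F @ beta
            new_ll = weighted_poisson_loglik(z, mu, w)
            new_alpha = beta / beta.sum()
            weights_stable = np.abs(new_alpha - alpha).max() <= 1e-10
            ll_flat = new_ll - ll <= tol * (abs(new_ll) + 1.0)
            # exact-fit instances sit on a likelihood plateau where boundary
            # components decay sublinearly; a machine-flat likelihood is then
            # the only reachable stopping signal
            ll_machine_flat = new_ll - ll <= 1e-14 * (abs(new_ll) + 1.0)
            if (ll_flat and weights_stable) or ll_machine_flat:
                converged = True
                ll = new_ll
                break
            ll = new_ll
            alpha = new_alpha
    mu = F @ beta
    ll = weighted_poisson_loglik(z, mu, w)
    return beta, ll, it, converged


def _pseudo_r2(z: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """Deviance pseudo-R²: 1 - D(fit)/D(null), null = weighted-mean intercept."""
    mu_null = np.full_like(z, np.sum(w * z) / np.sum(w))
    d_null = weighted_poisson_deviance(z, mu_null, w)
    d_fit = weighted_poisson_deviance(z, mu, w)
    if d_null <= 1e-12:
        return 1.0 if d_fit <= 1e-12 else 0.0
    return float(np.clip(1.0 - d_fit / d_null, 0.0, 1.0))


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_signals(
    bulk: BulkSample,
    reference: ReferenceProfileSet,
    drop_genes: Sequence[str] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_genes: int = MIN_GENES_WARN,
    stage: str = "",
) -> SignalFit:
    """Fit one bulk transcriptome as reference contributions + unexplained.

    Returns a :class:`SignalFit` whose contributions and intercept sum to 1.
    Non-convergence within ``max_iter`` is returned (not raised) with
    ``converged=False`` and a warning.
    """
    z, F, w, genes, gene_hash = _assemble_instance(bulk, reference, drop_genes, min_genes)
    G = len(z)
    A = np.column_stack([F, np.full(G, 1.0 / G)])
    beta, ll, n_iter, converged = _fit_mixture(z, A, w, max_iter, tol)
    if not converged:
        warnings.warn(
            f"sample {bulk.sample_id}: fit did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    total = beta.sum()
    alpha = beta / total
    mu = A @ beta
    fit = SignalFit(
        sample_id=bulk.sample_id,
        contributions=pd.Series(alpha[:-1], index=reference.cell_types),
        intercept=float(alpha[-1]),
        pseudo_r2=_pseudo_r2(z, mu, w),
        n_iter=n_iter,
        converged=converged,
        log_likelihood=ll,
        gene_set_hash=gene_hash,
        stage=stage,
    )
    logger.debug(
        "fit %s: rho=%.4f w0=%.4f iters=%d converged=%s",
        bulk.sample_id, fit.pseudo_r2, fit.intercept, n_iter, converged,
    )
    return fit


def fit_signals_excluding(
    bulk: BulkSample,
    reference: ReferenceProfileSet,
    drop_genes: Sequence[str],
    **kwargs,
) -> SignalFit:
    """Refit with named genes dropped (weight 0) — the AFP-exclusion mechanism."""
    return fit_signals(bulk, reference, drop_genes=drop_genes, **kwargs)


def summarize_groups(
    fit: SignalFit,
    reference: ReferenceProfileSet,
    include_gastrulation: bool = True,
) -> SummaryScore:
    """Sum contributions by developmental group (foetalness = foetal sum, etc.)."""
    meta = reference.meta.set_index("cell_type")
    scores: dict[str, float] = {}
    for ct, val in fit.contributions.items():
        if ct not in meta.index or pd.isna(meta.loc[ct, "group"]):
            raise ValueError(f"cell type {ct!r} has no group label")
        g = str(meta.loc[ct, "group"])
        scores[g] = scores.get(g, 0.0) + float(val)
    scores["unexplained"] = fit.intercept
    return SummaryScore(fit.sample_id, scores, include_gastrulation)


def progressive_fit(
    bulk: BulkSample,
    reference: ReferenceProfileSet,
    stages: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    **kwargs,
) -> list[SignalFit]:
    """Fit under increasingly complete references (one fit per group subset).

    ``stages`` maps stage name -> collection of group labels (or is a plain
    sequence of group collections, named stage_0..). Gene weighting is
    identical across stages; only the reference columns differ.
    """
    if not isinstance(stages, Mapping):
        stages = {f"stage_{i}": s for i, s in enumerate(stages)}
    fits = []
    for name, groups in stages.items():
        groups = set(groups)
        keep = [
            ct for ct in reference.cell_types if reference.group_of(ct) in groups
        ]
        if not keep:
            raise ValueError(f"stage {name!r} selects zero reference cell types")
        sub = reference.subset_types(keep)
        fits.append(fit_signals(bulk, sub, stage=name, **kwargs))
    return fits


# ---------------------------------------------------------------------------
# independent reference maximizer (brute-force grid)
# ---------------------------------------------------------------------------

def _simplex_grid(k: int, n: int) -> np.ndarray:
    """All (k,) non-negative integer vectors summing to n, as fractions of n."""
    if k == 1:
        return np.array([[1.0]])
    axes = [np.arange(n + 1)] * (k - 1)
    mesh = np.meshgrid(*axes, indexing="ij")
    free = np.column_stack([m.ravel() for m in mesh])
    s = free.sum(axis=1)
    ok = s <= n
    return np.column_stack([free[ok], n - s[ok]]).astype(float) / n


def grid_search_fit(
    z: np.ndarray,
    F: np.ndarray,
    w: np.ndarray | None = None,
    resolution: float = 1e-3,
    coarse: float = 1e-2,
) -> tuple[np.ndarray, float]:
    """Brute-force maximizer over the weight simplex at a fixed grid resolution.

    Profiles the overall scale out analytically: for mixture m(alpha) the
    optimal scale is s = sum(w z)/sum(w m), so only the simplex of normalized
    weights (including the intercept) is enumerated. For three or more free
    dimensions a coarse pass precedes a local fine pass — sound here because
    the profiled objective is the restriction of a concave problem, so the
    optimum basin is unique. Returns (weights incl. intercept, log-likelihood).
    """
    z = np.asarray(z, dtype=float)
    G = len(z)
    w = np.ones(G) if w is None else np.asarray(w, dtype=float)
    A = np.column_stack([np.asarray(F, dtype=float), np.full(G, 1.0 / G)])
    K = A.shape[1]

    def evaluate(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = points @ A.T  # (P, G)
        s = np.sum(w * z) / (m @ w)
        mu = m * s[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(z > 0, z * np.log(mu), 0.0)
        ll = (term - mu) @ w
        return points, ll

    n_fine = int(round(1.0 / resolution))
    if K <= 3:
        pts, ll = evaluate(_simplex_grid(K, n_fine))
        best = int(np.argmax(ll))
        return pts[best], float(ll[best])
    # coarse pass, then a fine window around the coarse optimum
    n_coarse = int(round(1.0 / coarse))
    pts, ll = evaluate(_simplex_grid(K, n_coarse))
    center = pts[int(np.argmax(ll))]
    window = 2 * coarse
    axes = []
    for c in center[:-1]:
        lo = max(0.0, c - window)
        hi = min(1.0, c + window)
        axes.append(np.arange(round(lo / resolution), round(hi / resolution) + 1) * resolution)
    mesh = np.meshgrid(*axes, indexing="ij")
    free = np.column_stack([m.ravel() for m in mesh])
    last = 1.0 - free.sum(axis=1)
    ok = last >= -1e-12
    fine = np.column_stack([free[ok], np.clip(last[ok], 0.0, 1.0)])
    pts2, ll2 = evaluate(fine)
    best = int(np.argmax(ll2))
    return pts2[best], float(ll2[best])
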