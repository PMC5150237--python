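"""Mate-choice inference on the one-row-per-candidate choice table.

Each offspring is one maternal choice event: its table block has one row
per genotyped candidate male, with ``CHOSEN = 1`` on the assigned father's
row. Models are binomial GLMMs,

    CHOSEN ~ MHC_INDEX [* factor(TAARlocus)]
             + (1|COLONY) + (1|YEAR) + (1|CANDIDATEFATHER) + (1|MOTHER),

fitted by Laplace-approximated ML (:mod:`mhcmate.glmm`). Fixed-effect
significance comes from parametric-bootstrap likelihood-ratio tests: the
null distribution of the LRT statistic is generated by simulating
responses (random effects + binomial noise) from the fitted null model and
refitting both models on each replicate.

Inclusion rules differ by index class: diversity indices (MALDiv, MAADiv)
need no maternal genotype, dissimilarity indices do — which is why a
diversity analysis can retain more couples than a dissimilarity one on the
same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import substream
from .glmm import MixedLogitFit, fit_mixed_logit
from .indices import AADistanceMatrix, DISSIMILARITY_INDICES, compute_index
from .types import ChoiceEvent, GenotypeTable

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "LrtResult",
    "build_choice_table",
    "fit_choice_glmm",
    "simulate_response",
    "lrt_parametric_bootstrap",
    "predicted_choice_curve",
    "taar_interaction_test",
    "attach_taar_factor",
]

RANDOM_FACTORS = ("COLONY", "YEAR", "CANDIDATEFATHER", "MOTHER")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure; random effects are always the four crossed
    intercepts. ``factor`` requires a ``TAARlocus`` column in the table."""

    index: bool = True
    factor: bool = False
    interaction: bool = False

    def __post_init__(self):
        if self.interaction and not (self.index and self.factor):
            raise ValueError("interaction requires both main effects")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.index <= other.index
            and self.factor <= other.factor
            and self.interaction <= other.interaction
        )


def build_choice_table(
    events: list[ChoiceEvent],
    genotypes: GenotypeTable,
    gene: str,
    index_name: str,
    D: AADistanceMatrix | None = None,
    mu_mode: str = "within_symdiff",
) -> tuple[pd.DataFrame, dict]:
    """Flatten events into the CHOSEN table for one gene and one index.

    An event is included iff its father is genotyped, at least one further
    candidate is genotyped, and (for dissimilarity indices) the mother is
    genotyped; rows with undefined index values are excluded and logged,
    and an event whose father row is undefined is dropped entirely.
    """
    needs_mother = index_name in DISSIMILARITY_INDICES
    rows = []
    log = {
        "events_in": len(events),
        "events_out": 0,
        "no_father_genotype": 0,
        "no_mother_genotype": 0,
        "too_few_candidates": 0,
        "father_index_undefined": 0,
        "rows_undefined_dropped": 0,
    }
    for ev in events:
        mset = genotypes.get(ev.mother_id, gene)
        if needs_mother and mset is None:
            log["no_mother_genotype"] += 1
            continue
        if genotypes.get(ev.father_id, gene) is None:
            log["no_father_genotype"] += 1
            continue
        cands = [c for c in ev.candidate_ids if genotypes.get(c, gene) is not None]
        if len(cands) < 2:
            log["too_few_candidates"] += 1
            continue
        block = []
        father_ok = False
        for c in cands:
            iv = compute_index(
                index_name, mset if needs_mother else None,
                genotypes.get(c, gene), D, mu_mode=mu_mode,
            )
            if not iv.defined:
                if c == ev.father_id:
                    father_ok = False
                    break
                log["rows_undefined_dropped"] += 1
                continue
            if c == ev.father_id:
                father_ok = True
            block.append(
                {
                    "OFFSPRING": ev.offspring_id,
                    "CANDIDATE": c,
                    "CHOSEN": int(c == ev.father_id),
                    "MHC_INDEX": iv.value,
                    "COLONY": ev.colony,
                    "YEAR": ev.conception_year,
                    "CANDIDATEFATHER": c,
                    "MOTHER": ev.mother_id,
                }
            )
        if not father_ok:
            log["father_index_undefined"] += 1
            continue
        if len(block) < 2:
            log["too_few_candidates"] += 1
            continue
        rows.extend(block)
        log["events_out"] += 1
    cols = ["OFFSPRING", "CANDIDATE", "CHOSEN", "MHC_INDEX", "COLONY", "YEAR",
            "CANDIDATEFATHER", "MOTHER"]
    table = pd.DataFrame(rows, columns=cols)
    return table, log


def _design(table: pd.DataFrame, spec: ModelSpec, standardize: bool):
    names = ["(Intercept)"]
    n = len(table)
    cols = [np.ones(n)]
    center, scale = 0.0, 1.0
    if spec.index:
        x = table["MHC_INDEX"].to_numpy(dtype=float)
        if standardize:
            center, scale = float(x.mean()), float(x.std() or 1.0)
            x = (x - center) / scale
        cols.append(x)
        names.append("MHC_INDEX")
    levels: list = []
    if spec.factor:
        fac = table["TAARlocus"].astype(str)
        levels = sorted(fac.unique())
        if len(levels) < 2:
            raise ValueError("TAARlocus factor is constant: no contrast to test")
        for lv in levels[1:]:
            cols.append((fac == lv).to_numpy(dtype=float))
            names.append(f"TAARlocus[{lv}]")
        if spec.interaction:
            x = cols[1]
            for lv in levels[1:]:
                cols.append(x * (fac == lv).to_numpy(dtype=float))
                names.append(f"MHC_INDEX:TAARlocus[{lv}]")
    return np.column_stack(cols), names, levels, (center, scale)


def _factor_codes(table: pd.DataFrame):
    out = []
    for f in RANDOM_FACTORS:
        vals = table[f].astype(str).to_numpy()
        levels = np.array(sorted(set(vals)))
        lookup = {lv: i for i, lv in enumerate(levels)}
        codes = np.array([lookup[v] for v in vals], dtype=np.int64)
        out.append((f, codes, len(levels)))
    return out


@dataclass
class GlmmFit:
    """A fitted choice GLMM plus everything needed to simulate from it."""

    result: MixedLogitFit
    spec: ModelSpec
    X: np.ndarray
    y: np.ndarray
    factors: list
    index_center: float = 0.0
    index_scale: float = 1.0
    factor_levels: list = field(default_factory=list)

    @property
    def slope(self) -> float:
        """Slope on MHC_INDEX, on the original (unstandardized) scale."""
        j = self.result.beta_names.index("MHC_INDEX")
        return float(self.result.beta[j] / self.index_scale)

    @property
    def slope_se(self) -> float:
        j = self.result.beta_names.index("MHC_INDEX")
        return float(self.result.beta_se[j] / self.index_scale)

    @property
    def converged(self) -> bool:
        return self.result.converged


def fit_choice_glmm(
    table: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    seed: int | None = None,
    standardize: bool = False,
    **fit_kw,
) -> GlmmFit:
    """Fit one model on a choice table. The fit itself is deterministic;
    ``seed`` is accepted for interface symmetry with the resampling ops."""
    if len(table) == 0:
        raise ValueError("empty choice table")
    X, names, levels, (center, scale) = _design(table, spec, standardize)
    factors = _factor_codes(table)
    y = table["CHOSEN"].to_numpy(dtype=float)
    res = fit_mixed_logit(X, y, factors, beta_names=names, **fit_kw)
    return GlmmFit(
        result=res, spec=spec, X=X, y=y, factors=factors,
        index_center=center, index_scale=scale, factor_levels=levels,
    )


def simulate_response(fit: GlmmFit, rng: np.random.Generator) -> np.ndarray:
    """Parametric simulation: fresh Gaussian random effects + binomial noise."""
    eta = fit.X @ fit.result.beta
    for f, (name, codes, nl) in enumerate(fit.factors):
        u = fit.result.sigma[f] * rng.standard_normal(nl)
        eta = eta + u[codes]
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    return (rng.random(len(eta)) < p).astype(float)


@dataclass
class LrtResult:
    statistic: float
    null_statistics: np.ndarray
    p_value: float
    n_boot: int
    n_failed: int
    full_fit: GlmmFit
    null_fit: GlmmFit
    flagged: bool = False

    def __repr__(self):
        return (
            f"LrtResult(statistic={self.statistic:.4f}, p={self.p_value:.4g}, "
            f"n_boot={self.n_boot}, n_failed={self.n_failed})"
        )


def _refit(table_y, fit: GlmmFit, **kw) -> MixedLogitFit:
    kw.setdefault("compute_se", False)
    kw.setdefault("pirls_tol", 1e-8)
    return fit_mixed_logit(
        fit.X, table_y, fit.factors,
        beta_names=fit.result.beta_names,
        start_sigma=fit.result.sigma, warm=True, **kw,
    )


def lrt_parametric_bootstrap(
    table: pd.DataFrame,
    full_spec: ModelSpec,
    null_spec: ModelSpec,
    n_boot: int = 1000,
    seed: int = 0,
    corrected: bool = True,
    boot_xatol: float = 2e-2,
    boot_fatol: float = 5e-3,
    boot_maxfev: int = 150,
    **fit_kw,
) -> LrtResult:
    """Parametric-bootstrap LRT of ``full_spec`` against nested ``null_spec``.

    p = (1 + #{T_b >= T_obs}) / (n_boot + 1) over converged replicates
    (``corrected=False`` gives the plain proportion). The result is flagged
    when more than 5% of replicate refits fail to converge.
    """
    if not null_spec.is_nested_in(full_spec):
        raise ValueError("null_spec must be nested in full_spec")
    rng = substream(seed, "lrt-bootstrap")
    full = fit_choice_glmm(table, full_spec, **fit_kw)
    null = fit_choice_glmm(table, null_spec, **fit_kw)
    t_obs = null.result.m2ll - full.result.m2ll
    stats = np.empty(n_boot)
    ok = np.zeros(n_boot, dtype=bool)
    for b in range(n_boot):
        y_b = simulate_response(null, rng)
        rf = _refit(y_b, full, xatol=boot_xatol, fatol=boot_fatol, maxfev=boot_maxfev)
        rn = _refit(y_b, null, xatol=boot_xatol, fatol=boot_fatol, maxfev=boot_maxfev)
        stats[b] = rn.m2ll - rf.m2ll
        ok[b] = rf.converged and rn.converged
    null_stats = stats[ok]
    n_eff = int(ok.sum())
    n_failed = n_boot - n_eff
    if n_eff == 0:
        raise RuntimeError("all bootstrap refits failed to converge")
    hits = int((null_stats >= t_obs - 1e-9).sum())
    p = (1 + hits) / (n_eff + 1) if corrected else max(hits, 0) / n_eff
    if not corrected and hits == 0:
        p = 0.0
    return LrtResult(
        statistic=float(t_obs),
        null_statistics=null_stats,
        p_value=float(p),
        n_boot=n_eff,
        n_failed=n_failed,
        full_fit=full,
        null_fit=null,
        flagged=n_failed > 0.05 * n_boot,
    )


def predicted_choice_curve(
    fit: GlmmFit,
    index_grid: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-effects-only choice probabilities over an index grid, with a
    percentile 95% band from parametric-bootstrap refits of the model."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if not fit.spec.index or fit.spec.factor:
        raise ValueError("curve prediction expects the plain index model")
    rng = substream(seed, "curve-bootstrap")
    grid = np.asarray(index_grid, dtype=float)
    xs = (grid - fit.index_center) / fit.index_scale
    obs_lo = fit.X[:, 1].min() if fit.X.shape[1] > 1 else -np.inf
    obs_hi = fit.X[:, 1].max() if fit.X.shape[1] > 1 else np.inf
    extrapolated = (xs < obs_lo) | (xs > obs_hi)

    def predict(beta):
        return 1.0 / (1.0 + np.exp(-(beta[0] + beta[1] * xs)))

    preds = np.empty((n_boot, len(grid)))
    kept = 0
    for _ in range(n_boot):
        y_b = simulate_response(fit, rng)
        rf = _refit(y_b, fit)
        if not rf.converged:
            continue
        preds[kept] = predict(rf.beta)
        kept += 1
    if kept == 0:
        raise RuntimeError("all bootstrap refits failed")
    lo, hi = np.percentile(preds[:kept], [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "index": grid,
            "prob": predict(fit.result.beta),
            "lo": lo,
            "hi": hi,
            "extrapolated": extrapolated,
        }
    )


def bootstrap_slope_ci(
    fit: GlmmFit,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "normal",
) -> tuple[float, float]:
    """Parametric-bootstrap CI for the MHC_INDEX slope.

    ``normal`` uses the bootstrap SD around the point estimate (stable at
    modest n_boot); ``percentile`` uses empirical quantiles.
    """
    rng = substream(seed, "slope-ci-bootstrap")
    j = fit.result.beta_names.index("MHC_INDEX")
    slopes = []
    for _ in range(n_boot):
        y_b = simulate_response(fit, rng)
        rf = _refit(y_b, fit)
        if rf.converged:
            slopes.append(rf.beta[j] / fit.index_scale)
    if not slopes:
        raise RuntimeError("all bootstrap refits failed")
    slopes = np.asarray(slopes)
    from scipy.stats import norm

    if method == "normal":
        z = norm.ppf(0.5 + level / 2)
        return (fit.slope - z * slopes.std(ddof=1), fit.slope + z * slopes.std(ddof=1))
    lo, hi = np.percentile(slopes, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


def attach_taar_factor(
    table: pd.DataFrame,
    taar_genotypes: GenotypeTable,
    taar_gene: str,
    factor_mode: str = "het_status",
    allele_id: str | None = None,
) -> pd.DataFrame:
    """Add the maternal TAAR factor column (a property of the MOTHER,
    attached to all her rows)."""
    out = table.copy()
    levels = []
    for m in out["MOTHER"]:
        g = taar_genotypes.get(m, taar_gene)
        if g is None:
            raise ValueError(f"mother {m} has no {taar_gene} genotype")
        if factor_mode == "het_status":
            levels.append("het" if len(g) == 2 else "hom")
        elif factor_mode == "allele_presence":
            if allele_id is None:
                raise ValueError("allele_presence mode needs allele_id")
            levels.append("carrier" if allele_id in g else "noncarrier")
        else:
            raise ValueError(f"unknown factor_mode {factor_mode!r}")
    out["TAARlocus"] = levels
    if out["TAARlocus"].nunique() < 2:
        raise ValueError("TAARlocus factor is constant across mothers")
    return out


def taar_interaction_test(
    table: pd.DataFrame,
    taar_genotypes: GenotypeTable,
    taar_gene: str,
    factor_mode: str = "het_status",
    allele_id: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    **kw,
) -> LrtResult:
    """Does the maternal TAAR factor modulate the index effect?

    Compares MHC_INDEX * factor against MHC_INDEX + factor by
    parametric-bootstrap LRT.
    """
    tab = attach_taar_factor(table, taar_genotypes, taar_gene, factor_mode, allele_id)
    full = ModelSpec(index=True, factor=True, interaction=True)
    null = ModelSpec(index=True, factor=True, interaction=False)
    return lrt_parametric_bootstrap(tab, full, null, n_boot=n_boot, seed=seed, **kw)
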