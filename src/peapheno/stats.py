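"""Statistical layer: ANOVA, variance components, heritability, CV,
correlation networks and PCA for genotype x condition trait tables.

The experiment is a balanced completely randomized design: g accessions x
c conditions x r replicates. The classical two-way decomposition gives the
sums of squares; the all-random variance components follow from the
expected mean squares

    E[MS_E]  = s2_e
    E[MS_GC] = s2_e + r s2_gc
    E[MS_G]  = s2_e + r s2_gc + r c s2_g
    E[MS_C]  = s2_e + r s2_gc + r g s2_c

whose method-of-moments solution coincides with REML for balanced data when
all estimates are interior (negative solutions are truncated at zero and
flagged). Broad-sense heritability defaults to the plot basis

    h2 = s2_g / (s2_g + s2_gc + s2_e)

with the entry-mean basis s2_g / (s2_g + s2_gc/c + s2_e/(c r)) as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from peapheno.reference import TRAIT_CATEGORIES

TERMS = ("genotype", "condition", "genotype:condition", "residual")


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaTable:
    """Two-way ANOVA decomposition for one trait on a balanced CRD."""

    table: pd.DataFrame  # index TERMS; columns df, sum_sq, mean_sq, F, p
    g: int
    c: int
    r: int
    trait: str = ""

    @property
    def total_ss(self) -> float:
        return float(self.table["sum_sq"].sum())


def _balanced_cube(table: pd.DataFrame, trait: str) -> tuple[np.ndarray, list, list]:
    """Reshape a long trait table into a (g, c, r) cube; error if unbalanced."""
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    counts = sub.groupby(["accession", "condition"])["value"].count()
    r = int(counts.iloc[0])
    accs = sorted(sub["accession"].unique())
    conds = sorted(sub["condition"].unique())
    if counts.nunique() != 1 or len(counts) != len(accs) * len(conds):
        raise ValueError(
            f"unbalanced layout for trait {trait!r}: every accession x condition "
            "cell must have the same replicate count; drop incomplete cells or "
            "use a mixed-model tool for unbalanced data"
        )
    if r < 2:
        raise ValueError(f"need >= 2 replicates per cell, got {r}")
    cube = (
        sub.sort_values(["accession", "condition", "replicate"])["value"]
        .to_numpy()
        .reshape(len(accs), len(conds), r)
    )
    return cube, accs, conds


def two_way_anova(table: pd.DataFrame, trait: str) -> AnovaTable:
    """Classical two-way ANOVA (genotype, condition, interaction, residual).

    F ratios test each effect against the residual mean square; when the
    residual SS is zero the F statistics are reported as NaN.
    """
    cube, accs, conds = _balanced_cube(table, trait)
    g, c, r = cube.shape
    grand = cube.mean()
    m_g = cube.mean(axis=(1, 2))
    m_c = cube.mean(axis=(0, 2))
    m_gc = cube.mean(axis=2)

    ss_g = c * r * float(((m_g - grand) ** 2).sum())
    ss_c = g * r * float(((m_c - grand) ** 2).sum())
    ss_gc = r * float(
        ((m_gc - m_g[:, None] - m_c[None, :] + grand) ** 2).sum()
    )
    ss_e = float(((cube - m_gc[:, :, None]) ** 2).sum())

    df = np.array([g - 1, c - 1, (g - 1) * (c - 1), g * c * (r - 1)], dtype=float)
    ss = np.array([ss_g, ss_c, ss_gc, ss_e])
    ms = ss / df
    if ms[3] > 0:
        F = np.array([ms[0] / ms[3], ms[1] / ms[3], ms[2] / ms[3], np.nan])
        p = np.array([sps.f.sf(F[i], df[i], df[3]) for i in range(3)] + [np.nan])
    else:
        F = np.full(4, np.nan)
        p = np.full(4, np.nan)

    frame = pd.DataFrame(
        {"df": df.astype(int), "sum_sq": ss, "mean_sq": ms, "F": F, "p": p},
        index=list(TERMS),
    )
    return AnovaTable(table=frame, g=g, c=c, r=r, trait=trait)


# ---------------------------------------------------------------------------
# variance components and heritability


@dataclass
class VarianceDecomposition:
    """All-random variance components of one trait, with standard errors."""

    sigma2_g: float
    sigma2_c: float
    sigma2_gc: float
    sigma2_e: float
    se: dict = field(default_factory=dict)
    truncated: list = field(default_factory=list)
    g: int = 0
    c: int = 0
    r: int = 0
    trait: str = ""

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_c + self.sigma2_gc + self.sigma2_e

    def as_dict(self) -> dict[str, float]:
        return {
            "genotype": self.sigma2_g,
            "condition": self.sigma2_c,
            "genotype:condition": self.sigma2_gc,
            "residual": self.sigma2_e,
        }


def estimate_variance_components(anova: AnovaTable) -> VarianceDecomposition:
    """Method-of-moments (EMS) variance components from a balanced ANOVA.

    Negative raw solutions are truncated at zero and listed in
    ``truncated``; where truncation occurs the estimates can differ from
    iterative REML. Standard errors come from the delta method on the mean
    squares, using Var(MS) = 2 MS^2 / df.
    """
    t = anova.table
    if (t["df"] <= 0).any():
        raise ValueError("every term needs positive degrees of freedom")
    g, c, r = anova.g, anova.c, anova.r
    ms = t["mean_sq"]
    ms_g, ms_c, ms_gc, ms_e = (
        ms["genotype"], ms["condition"], ms["genotype:condition"], ms["residual"]
    )

    raw = {
        "residual": ms_e,
        "genotype:condition": (ms_gc - ms_e) / r,
        "genotype": (ms_g - ms_gc) / (r * c),
        "condition": (ms_c - ms_gc) / (r * g),
    }
    truncated = [k for k, v in raw.items() if v < 0]
    est = {k: max(v, 0.0) for k, v in raw.items()}

    var_ms = {term: 2.0 * ms[term] ** 2 / t.loc[term, "df"] for term in TERMS}
    se = {
        "residual": np.sqrt(var_ms["residual"]),
        "genotype:condition": np.sqrt(
            (var_ms["genotype:condition"] + var_ms["residual"]) / r**2
        ),
        "genotype": np.sqrt(
            (var_ms["genotype"] + var_ms["genotype:condition"]) / (r * c) ** 2
        ),
        "condition": np.sqrt(
            (var_ms["condition"] + var_ms["genotype:condition"]) / (r * g) ** 2
        ),
    }
    return VarianceDecomposition(
        sigma2_g=est["genotype"],
        sigma2_c=est["condition"],
        sigma2_gc=est["genotype:condition"],
        sigma2_e=est["residual"],
        se=se,
        truncated=truncated,
        g=g, c=c, r=r, trait=anova.trait,
    )


def heritability(vc: VarianceDecomposition, basis: str = "plot") -> float:
    """Broad-sense heritability on the plot or entry-mean basis, in [0, 1].

    plot:       h2 = s2_g / (s2_g + s2_gc + s2_e)
    entry-mean: h2 = s2_g / (s2_g + s2_gc/c + s2_e/(c r))

    NaN when the denominator is zero.
    """
    if basis == "plot":
        denom = vc.sigma2_g + vc.sigma2_gc + vc.sigma2_e
    elif basis == "entry-mean":
        if vc.c < 1 or vc.r < 1:
            raise ValueError("entry-mean basis needs the design counts c, r")
        denom = vc.sigma2_g + vc.sigma2_gc / vc.c + vc.sigma2_e / (vc.c * vc.r)
    else:
        raise ValueError(f"unknown heritability basis {basis!r}")
    if denom <= 0:
        warnings.warn("heritability undefined: zero total variance", stacklevel=2)
        return float("nan")
    return float(np.clip(vc.sigma2_g / denom, 0.0, 1.0))


def relative_contributions(vc: VarianceDecomposition,
                           include_residual: bool = True) -> dict[str, float]:
    """Each variance component as a percent of their sum (sums to 100)."""
    comps = vc.as_dict()
    if not include_residual:
        comps = {k: v for k, v in comps.items() if k != "residual"}
    total = sum(comps.values())
    if total <= 0:
        warnings.warn("relative contributions undefined: zero total variance", stacklevel=2)
        return {k: float("nan") for k in comps}
    return {k: 100.0 * v / total for k, v in comps.items()}


def variance_decomposition(table: pd.DataFrame, trait: str,
                           basis: str = "plot") -> VarianceDecomposition:
    """ANOVA -> components -> h2 and contributions, as one convenience call."""
    vc = estimate_variance_components(two_way_anova(table, trait))
    vc.se["h2"] = float("nan")  # SE of h2 not propagated in the convenience path
    return vc


# ---------------------------------------------------------------------------
# descriptive statistics


def coefficient_of_variation(table: pd.DataFrame, trait: str) -> pd.Series:
    """CV (%) = sd / mean x 100 within each condition (sample sd, ddof=1)."""
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    out = {}
    for cond, vals in sub.groupby("condition")["value"]:
        mean = vals.mean()
        if mean == 0:
            warnings.warn(f"CV undefined for {trait!r}/{cond!r}: zero mean", stacklevel=2)
            out[cond] = float("nan")
        else:
            out[cond] = float(vals.std(ddof=1) / mean * 100.0)
    return pd.Series(out, name=trait)


# ---------------------------------------------------------------------------
# correlations


def to_wide(table: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Pivot the long table to per-plant rows x trait columns."""
    sub = table if condition is None else table[table["condition"] == condition]
    wide = sub.pivot_table(
        index=["accession", "condition", "replicate"],
        columns="trait", values="value", aggfunc="mean",
    )
    wide.columns.name = None
    return wide


def correlation_matrix(table: pd.DataFrame, condition: str,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-plant records in one condition.

    Constant traits are excluded with a warning; pairs with fewer than
    ``min_pairs`` complete records are NaN.
    """
    wide = to_wide(table, condition)
    constant = [t for t in wide.columns if wide[t].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"excluding constant traits from correlations: {constant}", stacklevel=2)
        wide = wide.drop(columns=constant)
    return wide.corr(method="pearson", min_periods=min_pairs)


def correlation_network(table: pd.DataFrame, condition: str,
                        draw_threshold: float = 0.30,
                        strong_threshold: float = 0.60) -> nx.Graph:
    """Trait correlation network for one condition.

    Nodes carry a ``category`` attribute (biomass / architectural /
    physiological); edges exist where |r| >= draw_threshold and carry
    ``r``, ``sign`` (positive/negative) and ``strength`` (strong/weak,
    split at strong_threshold).
    """
    corr = correlation_matrix(table, condition)
    G = nx.Graph(condition=condition)
    for trait in corr.columns:
        G.add_node(trait, category=TRAIT_CATEGORIES.get(trait, "other"))
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r) or abs(r) < draw_threshold:
                continue
            G.add_edge(
                a, b, r=float(r),
                sign="positive" if r > 0 else "negative",
                strength="strong" if abs(r) >= strong_threshold else "weak",
            )
    return G


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PcaResult:
    """Correlation-matrix PCA of the standardized trait matrix."""

    loadings: pd.DataFrame  # traits x components, orthonormal columns
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    dropped: tuple[str, ...] = ()


def pca_biplot(table: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of per-plant records, standardized jointly across conditions.

    Columns are centered and scaled to unit variance; the eigendecomposition
    of the correlation matrix gives loadings (sign-fixed so each component's
    largest-magnitude loading is positive), scores and explained-variance
    proportions. Zero-variance columns are dropped and incomplete rows
    removed, both with warnings.
    """
    wide = to_wide(table)
    dropped = tuple(t for t in wide.columns if not (wide[t].std(ddof=0) > 0))
    if dropped:
        warnings.warn(f"dropping zero-variance traits from PCA: {list(dropped)}", stacklevel=2)
        wide = wide.drop(columns=list(dropped))
    n_before = len(wide)
    wide = wide.dropna()
    if len(wide) < n_before:
        warnings.warn(f"dropping {n_before - len(wide)} incomplete rows from PCA", stacklevel=2)
    n, p = wide.shape
    if n <= p:
        warnings.warn(f"fewer samples ({n}) than traits ({p}): PCA is rank-deficient", stacklevel=2)

    Z = (wide - wide.mean()) / wide.std(ddof=1)
    corr = np.asarray(Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.maximum(eigvals[order], 0.0), eigvecs[:, order]

    # sign convention: largest-|loading| entry positive per component
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] *= -1

    k = n_components if n_components is not None else p
    comps = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(eigvecs[:, :k], index=wide.columns, columns=comps)
    scores = pd.DataFrame(Z.to_numpy() @ eigvecs[:, :k], index=wide.index, columns=comps)
    evr = eigvals / eigvals.sum() if eigvals.sum() > 0 else np.full(p, np.nan)
    return PcaResult(
        loadings=loadings, scores=scores,
        explained_variance_ratio=evr[:k], dropped=dropped,
    )
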