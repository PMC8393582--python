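"""Quantitative genetics: sib-based breeding values and genotype-trait tests.

The centrepiece is a statsmodels-style pair of objects.  :class:`SibModel`
holds a phenotyped progeny table with sire/dam links (a nested paternal
half-sib design); :meth:`SibModel.fit` estimates variance components by
nested random-effects ANOVA (Henderson expected mean squares), converts
the sire variance to additive variance via the half-sib covariance
(``sigma2_sire = sigma2_A / 4``), and predicts each progeny's breeding
value as

    EBV = 1/2 (a_sire + a_dam) + h2w * e

where parental values are heritability-shrunken family-mean deviations,
``e`` is the individual's deviation from its full-sib family mean, and the
within-family heritability ``h2w = 1/2 sigma2_A / sigma2_e`` shrinks that
Mendelian-sampling deviation.  Results (variance components, h2, EBVs,
summary table) live on :class:`SibResults`.

The rest of the module covers the per-locus genotype-trait toolkit:
Shapiro-Wilk normality check, one-way ANOVA with Duncan's multiple range
lettering, allele/genotype frequencies, and the additive / dominance /
recessive effect decomposition by single-predictor regressions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# sib-family model


@dataclass
class VarianceComponents:
    """Additive and residual variance with derived heritabilities (kg^2)."""

    sigma2_A: float
    sigma2_e: float
    sigma2_sire: float
    sigma2_dam: float
    sigma2_within: float
    h2: float
    h2_w: float


class SibModel:
    """Nested sire/dam random-effects model for a phenotyped progeny table.

    Parameters
    ----------
    data : DataFrame with columns ``id, sire, dam, mw`` (one row per
        phenotyped progeny).  Rows with missing phenotype are dropped.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"id", "sire", "dam", "mw"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        d = data.loc[data["mw"].notna(), ["id", "sire", "dam", "mw"]].copy()
        if d["sire"].eq("").any() or d["dam"].eq("").any():
            raise ValueError("all phenotyped individuals need sire and dam links")
        if d["sire"].nunique() < 2:
            raise ValueError("need >= 2 sire families to estimate variance components")
        self.data = d.reset_index(drop=True)

    @classmethod
    def from_population(
        cls, pop, sex: str | None = "M", adjust_sex: bool = False
    ) -> "SibModel":
        """Build from a simulated population.

        ``sex`` restricts to one stratum; ``sex=None`` with
        ``adjust_sex=True`` keeps both sexes but removes the sex mean
        difference (so full- and half-sib information from both sexes
        feeds the variance components, as in a mixed-sex flock).
        """
        ped = pop.pedigree
        d = ped[ped["mw"].notna()].copy()
        if sex is not None:
            d = d[d["sex"] == sex]
        elif adjust_sex:
            d["mw"] = d["mw"] - d.groupby("sex")["mw"].transform("mean") + d["mw"].mean()
        return cls(d[["id", "sire", "dam", "mw"]])

    def fit(self, h2w_definition: str = "residual") -> "SibResults":
        """Estimate variance components and predict EBVs.

        ``h2w_definition`` selects the denominator of the within-family
        heritability: ``"residual"`` uses the within-family residual
        variance (``1/2 sigma2_A / sigma2_e``); ``"phenotypic"`` uses the
        total phenotypic variance instead.
        """
        if h2w_definition not in ("residual", "phenotypic"):
            raise ValueError("h2w_definition must be 'residual' or 'phenotypic'")
        d = self.data
        y = d["mw"].to_numpy(float)
        n = len(y)
        mu = y.mean()

        vc = _nested_anova_components(d)
        sigma2_p = vc.sigma2_sire + vc.sigma2_dam + vc.sigma2_within
        denom = vc.sigma2_e if h2w_definition == "residual" else sigma2_p
        h2w = 0.5 * vc.sigma2_A / denom if denom > 0 else 0.0
        vc.h2_w = h2w

        # parental values: h2-shrunken family-mean deviations
        sire_dev = d.groupby("sire")["mw"].mean() - mu
        dam_dev = d.groupby("dam")["mw"].mean() - mu
        a_sire = vc.h2 * d["sire"].map(sire_dev).to_numpy(float)
        a_dam = vc.h2 * d["dam"].map(dam_dev).to_numpy(float)
        family_mean = d.groupby("dam")["mw"].transform("mean").to_numpy(float)
        e = y - family_mean
        ebv = 0.5 * (a_sire + a_dam) + h2w * e

        ebv_table = d[["id", "sire", "dam", "mw"]].copy()
        ebv_table["ebv"] = ebv
        return SibResults(
            model=self,
            vc=vc,
            ebv=ebv_table,
            n_obs=n,
            mean=mu,
            h2w_definition=h2w_definition,
        )


def _nested_anova_components(d: pd.DataFrame) -> VarianceComponents:
    """Henderson expected-mean-squares solution for the nested design.

    Sires are the outer and dams-within-sire the inner random factor;
    handles unbalanced family sizes via the standard coefficients.
    """
    y = d["mw"].to_numpy(float)
    n = len(y)
    mu = y.mean()
    by_dam = d.groupby(["sire", "dam"])["mw"]
    by_sire = d.groupby("sire")["mw"]
    n_ij = by_dam.size()
    n_i = by_sire.size()
    s = len(n_i)
    d_total = len(n_ij)

    ss_sire = float((n_i * (by_sire.mean() - mu) ** 2).sum())
    sire_mean_of = by_sire.mean()
    dam_means = by_dam.mean()
    sire_of_dam = dam_means.index.get_level_values("sire")
    ss_dam = float(
        (n_ij * (dam_means - sire_mean_of.loc[sire_of_dam].to_numpy()) ** 2).sum()
    )
    fam = d.groupby("dam")["mw"].transform("mean").to_numpy(float)
    ss_within = float(((y - fam) ** 2).sum())

    df_sire = s - 1
    df_dam = d_total - s
    df_within = n - d_total
    if df_within <= 0 or df_dam <= 0:
        raise ValueError("design too small: need >1 dam per sire and >1 progeny per dam")

    ms_sire = ss_sire / df_sire
    ms_dam = ss_dam / df_dam
    ms_within = ss_within / df_within

    sum_nij2_over_ni = float((n_ij**2 / n_i.loc[sire_of_dam].to_numpy()).sum())
    k1 = (n - sum_nij2_over_ni) / df_dam
    k2 = (sum_nij2_over_ni - float((n_ij**2).sum()) / n) / df_sire
    k3 = (n - float((n_i**2).sum()) / n) / df_sire

    sigma2_within = ms_within
    sigma2_dam = max((ms_dam - ms_within) / k1, 0.0)
    sigma2_sire = max((ms_sire - ms_within - k2 * sigma2_dam) / k3, 0.0)

    sigma2_a = 4.0 * sigma2_sire
    sigma2_p = sigma2_sire + sigma2_dam + sigma2_within
    h2 = min(sigma2_a / sigma2_p, 1.0) if sigma2_p > 0 else 0.0
    return VarianceComponents(
        sigma2_A=sigma2_a,
        sigma2_e=sigma2_within,
        sigma2_sire=sigma2_sire,
        sigma2_dam=sigma2_dam,
        sigma2_within=sigma2_within,
        h2=h2,
        h2_w=math.nan,
    )


@dataclass
class SibResults:
    """Fitted sib model: variance components, heritabilities and EBVs."""

    model: SibModel
    vc: VarianceComponents
    ebv: pd.DataFrame
    n_obs: int
    mean: float
    h2w_definition: str

    @property
    def h2(self) -> float:
        return self.vc.h2

    @property
    def h2_w(self) -> float:
        return self.vc.h2_w

    def select_extreme_groups(self, n_per_tail: int) -> tuple[list[str], list[str]]:
        """Bottom and top ``n_per_tail`` individuals by EBV (ties by id)."""
        return select_extreme_groups(self.ebv, n_per_tail)

    def summary(self) -> str:
        vc = self.vc
        lines = [
            "Sib-family model of marketing weight",
            "=" * 44,
            f"{'No. observations':<28}{self.n_obs:>16}",
            f"{'No. sire families':<28}{self.model.data['sire'].nunique():>16}",
            f"{'No. full-sib families':<28}{self.model.data['dam'].nunique():>16}",
            f"{'Trait mean (kg)':<28}{self.mean:>16.4f}",
            "-" * 44,
            f"{'sigma2_sire (kg^2)':<28}{vc.sigma2_sire:>16.5f}",
            f"{'sigma2_dam (kg^2)':<28}{vc.sigma2_dam:>16.5f}",
            f"{'sigma2_within (kg^2)':<28}{vc.sigma2_within:>16.5f}",
            f"{'sigma2_A = 4*sigma2_sire':<28}{vc.sigma2_A:>16.5f}",
            f"{'h2 (narrow-sense)':<28}{vc.h2:>16.4f}",
            f"{'h2w (' + self.h2w_definition + ')':<28}{vc.h2_w:>16.4f}",
            f"{'mean EBV (kg)':<28}{self.ebv['ebv'].mean():>16.5f}",
            "=" * 44,
        ]
        return "\n".join(lines)


def select_extreme_groups(
    ebv: pd.DataFrame, n_per_tail: int
) -> tuple[list[str], list[str]]:
    """Ids of the lowest and highest ``n_per_tail`` EBVs (ties by id)."""
    if n_per_tail * 2 > len(ebv):
        raise ValueError("n_per_tail exceeds half the population")
    ordered = ebv.sort_values(["ebv", "id"], kind="mergesort")
    low = ordered["id"].head(n_per_tail).tolist()
    high = ordered["id"].tail(n_per_tail).tolist()
    return low, high


# ---------------------------------------------------------------------------
# trait normality


def check_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a trait vector (n >= 3, non-constant)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values identical")
    w, p = stats.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# one-way ANOVA with Duncan's multiple range lettering


@dataclass
class AnovaResult:
    f: float
    p: float
    group_means: pd.Series
    group_se: pd.Series
    letters: dict[str, str]
    ms_error: float
    df_error: int


def genotype_trait_anova(
    genotypes, mw, alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA of trait on genotype class plus Duncan lettering.

    Classes with fewer than 2 observations are dropped from the analysis
    with a warning.  Groups sharing a letter are not separated by Duncan's
    multiple range test at protection level ``alpha``.
    """
    df = pd.DataFrame({"g": list(genotypes), "y": np.asarray(mw, float)}).dropna()
    sizes = df.groupby("g").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping genotype classes with < 2 observations: {small}",
                      stacklevel=2)
        df = df[~df["g"].isin(small)]
    groups = [g["y"].to_numpy() for _, g in df.groupby("g")]
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype classes with >= 2 observations")
    if np.ptp(df["y"].to_numpy()) == 0:
        raise ValueError("degenerate input: zero variance in trait")
    f, p = stats.f_oneway(*groups)
    means = df.groupby("g")["y"].mean()
    se = df.groupby("g")["y"].sem()
    n_total = len(df)
    k = len(groups)
    df_error = n_total - k
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_error = ss_within / df_error
    letters = duncan_letters(means, df.groupby("g").size(), ms_error, df_error, alpha)
    return AnovaResult(
        f=float(f),
        p=float(p),
        group_means=means,
        group_se=se,
        letters=letters,
        ms_error=ms_error,
        df_error=df_error,
    )


def duncan_letters(
    means: pd.Series,
    sizes: pd.Series,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan's multiple range test lettering.

    Ordered means are compared against the least significant range
    ``R_p = q(1 - alpha_p, p, df) * sqrt(MSE / n_h)`` with the stepwise
    protection level ``alpha_p = 1 - (1 - alpha)^(p - 1)`` for a span of
    ``p`` means (harmonic-mean group size for unequal n).  Any range
    contained in a non-significant range is itself non-significant;
    groups covered by a common non-significant stretch share a letter.
    """
    order = means.sort_values(ascending=False).index.tolist()
    m = means.loc[order].to_numpy(float)
    k = len(order)
    if k == 1:
        return {order[0]: "a"}
    n_h = stats.hmean(sizes.loc[order].to_numpy(float))
    # least significant range per span p = 2..k
    r = {
        p: stats.studentized_range.ppf(
            (1.0 - alpha) ** (p - 1), p, df_error
        )
        * math.sqrt(ms_error / n_h)
        for p in range(2, k + 1)
    }
    # significance of each span, protected: outer non-significant span
    # forces all inner spans non-significant
    sig = [[False] * k for _ in range(k)]
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = m[i] - m[j]
            s = diff > r[span]
            if span < k:
                # protection: if any enclosing span was non-significant, stay ns
                enclosing_ns = any(
                    not sig[i2][j2]
                    for i2 in range(0, i + 1)
                    for j2 in range(j, k)
                    if (j2 - i2) > (j - i)
                )
                if enclosing_ns:
                    s = False
            sig[i][j] = s

    # maximal non-significant stretches -> letters
    stretches: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i][j + 1]:
            j += 1
        stretches.append((i, j))
    # keep only maximal stretches
    maximal = [
        (i, j)
        for (i, j) in stretches
        if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2) in stretches)
    ]
    letters: dict[str, list[str]] = {g: [] for g in order}
    for idx, (i, j) in enumerate(sorted(maximal)):
        letter = chr(ord("a") + idx)
        for t in range(i, j + 1):
            letters[order[t]].append(letter)
    return {g: "".join(v) for g, v in letters.items()}


# ---------------------------------------------------------------------------
# frequencies


def compute_frequencies(genotypes) -> tuple[dict[str, float], dict[str, float]]:
    """Allele frequencies (gene counting) and genotype frequencies.

    ``genotypes`` is an iterable of two-character allele-pair strings
    (missing entries: None/NaN/"" are skipped).  Returns
    ``(allele_freqs, genotype_freqs)``; genotype keys are the sorted
    allele pairs.
    """
    called = [
        g for g in genotypes if isinstance(g, str) and len(g) == 2
    ]
    if not called:
        raise ValueError("no called genotypes")
    geno_counts: dict[str, int] = {}
    allele_counts: dict[str, int] = {}
    for g in called:
        key = "".join(sorted(g))
        geno_counts[key] = geno_counts.get(key, 0) + 1
        for a in key:
            allele_counts[a] = allele_counts.get(a, 0) + 1
    n = len(called)
    geno_freqs = {k: v / n for k, v in geno_counts.items()}
    allele_freqs = {k: v / (2 * n) for k, v in allele_counts.items()}
    return allele_freqs, geno_freqs


# ---------------------------------------------------------------------------
# additive / dominance / recessive decomposition


@dataclass
class EffectFit:
    """One coding's regression fit: slope (kg), SE, p and model AIC."""

    effect: float
    se: float
    p: float
    aic: float
    estimable: bool = True


@dataclass
class GenotypicEffects:
    locus_id: str
    additive: EffectFit
    dominance: EffectFit
    recessive: EffectFit


#: codings over alt-allele dosage {0, 1, 2}
EFFECT_CODINGS = {
    "additive": np.array([0.0, 1.0, 2.0]),
    "dominance": np.array([0.0, 1.0, 1.0]),
    "recessive": np.array([0.0, 0.0, 1.0]),
}


def regression_aic(rss: float, n: int, k_params: int) -> float:
    """Constant-free Gaussian AIC: ``n ln(RSS/n) + 2k``."""
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k_params


def _simple_fit(x: np.ndarray, y: np.ndarray) -> EffectFit:
    if np.ptp(x) == 0:
        return EffectFit(math.nan, math.nan, math.nan, math.nan, estimable=False)
    res = stats.linregress(x, y)
    n = len(y)
    resid = y - (res.intercept + res.slope * x)
    aic = regression_aic(float(resid @ resid), n, 2)
    return EffectFit(
        effect=float(res.slope),
        se=float(res.stderr),
        p=float(res.pvalue),
        aic=aic,
    )


def genotypic_effects(dosage, mw, locus_id: str = "") -> GenotypicEffects:
    """Additive / dominance / recessive regressions of trait on one locus.

    ``dosage`` counts copies of the alternative allele (0/1/2).  Each
    coding is a separate single-predictor OLS; a coding that is constant
    over the observed genotypes (e.g. recessive with no alt homozygotes)
    is flagged inestimable.  Raises on a monomorphic locus.
    """
    g = np.asarray(dosage, dtype=int)
    y = np.asarray(mw, dtype=float)
    keep = ~np.isnan(y)
    g, y = g[keep], y[keep]
    if np.ptp(g) == 0:
        raise ValueError(f"monomorphic locus {locus_id or '<unnamed>'}")
    fits = {
        name: _simple_fit(codes[g], y) for name, codes in EFFECT_CODINGS.items()
    }
    return GenotypicEffects(
        locus_id=locus_id,
        additive=fits["additive"],
        dominance=fits["dominance"],
        recessive=fits["recessive"],
    )
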