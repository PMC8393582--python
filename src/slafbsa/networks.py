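"""Multi-marker SNP networks by stepwise regression under mode codings.

Each biallelic locus enters the trait model through a numeric coding of
its three genotype classes {ref-hom, het, alt-hom}:

* ``additive``       (0, 1, 2)   het at the homozygote midpoint
* ``dominant_ref``   (0, 0, 2)   het indistinguishable from the ref hom
* ``dominant_alt``   (0, 2, 2)   het indistinguishable from the alt hom
* ``over_dominant``  (0, 1, 0)   het outside the homozygote interval

The best single-locus mode is chosen by AIC; loci whose best single-SNP
fit reaches p < alpha are candidates for stepwise (forward or backward)
multiple regression with a partial-F entry/stay threshold.  All surviving
subsets of size 2-4 whose members each stay significant jointly are
enumerated as SNP networks and ranked by AIC.  A network reports, per
member, the homozygote substitution effect: the model-predicted trait
change (in grams) when one homozygous class replaces the other, holding
the other members fixed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .quantgen import regression_aic

MODE_CODES: dict[str, tuple[float, float, float]] = {
    "additive": (0.0, 1.0, 2.0),
    "dominant_ref": (0.0, 0.0, 2.0),
    "dominant_alt": (0.0, 2.0, 2.0),
    "over_dominant": (0.0, 1.0, 0.0),
}

#: AIC tie-break preference (simpler genetic hypotheses first)
_MODE_ORDER = ("additive", "dominant_ref", "dominant_alt", "over_dominant")


@dataclass(frozen=True)
class ModeCoding:
    """A locus's genotype-to-number map for regression."""

    locus_id: str
    mode: str
    codes: tuple[float, float, float]

    def apply(self, dosage: np.ndarray) -> np.ndarray:
        return np.asarray(self.codes)[np.asarray(dosage, dtype=int)]


def _ols(X: np.ndarray, y: np.ndarray) -> dict:
    """Tiny OLS with per-coefficient t-tests; X excludes the intercept."""
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    k = Xd.shape[1]
    rank = np.linalg.matrix_rank(Xd)
    if rank < k:
        return {"singular": True}
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    dfe = n - k
    sigma2 = rss / dfe if dfe > 0 else math.nan
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfe)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return {
        "singular": False,
        "beta": beta,
        "se": se,
        "p": pvals,
        "rss": rss,
        "r2": r2,
        "aic": regression_aic(rss, n, k),
        "dfe": dfe,
        "fitted": Xd @ beta,
    }


def fit_single_snp_modes(
    dosage, mw, locus_id: str = ""
) -> tuple[ModeCoding, dict]:
    """Select the AIC-best genotype-mode coding for one locus.

    Fits the trait on each estimable coding and returns the winning
    :class:`ModeCoding` together with its fit dict (slope, p, AIC, R2).
    AIC ties break in favour of simpler modes (additive first).  Raises
    on a monomorphic locus.
    """
    g = np.asarray(dosage, dtype=int)
    y = np.asarray(mw, dtype=float)
    keep = ~np.isnan(y)
    g, y = g[keep], y[keep]
    if np.ptp(g) == 0:
        raise ValueError(f"monomorphic locus {locus_id or '<unnamed>'}")
    best: tuple[float, int, ModeCoding, dict] | None = None
    for rank, mode in enumerate(_MODE_ORDER):
        codes = MODE_CODES[mode]
        x = np.asarray(codes)[g]
        if np.ptp(x) == 0:
            continue
        fit = _ols(x[:, None], y)
        if fit["singular"]:
            continue
        key = (fit["aic"], rank)
        if best is None or key < (best[0], best[1]):
            best = (fit["aic"], rank, ModeCoding(locus_id, mode, codes), fit)
    if best is None:
        raise ValueError(f"no estimable mode coding at locus {locus_id}")
    return best[2], best[3]


@dataclass
class SnpNetworkModel:
    """One fitted SNP network: members, coefficients, diagnostics.

    ``substitution_effects_g`` maps member locus to the predicted
    marketing-weight change, in grams, of replacing the ref-homozygote by
    the alt-homozygote class (other members held at their sample means).
    Over-dominant members predict no homozygote contrast and are excluded
    from the report unless requested.
    """

    members: list[str]
    codings: dict[str, ModeCoding]
    intercept: float
    coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    r2: float
    aic: float
    fitted: np.ndarray
    actual: np.ndarray
    substitution_effects_g: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def predict(self, coded: pd.DataFrame) -> np.ndarray:
        x = coded[self.members].to_numpy(float)
        beta = np.array([self.coefficients[m] for m in self.members])
        return self.intercept + x @ beta

    def summary(self) -> str:
        lines = [
            f"SNP network ({self.size} loci)   R2={self.r2:.3f}  AIC={self.aic:.2f}",
            f"{'locus':<12}{'mode':<16}{'coef (kg)':>12}{'p':>12}{'subst. (g)':>12}",
        ]
        for m in self.members:
            sub = self.substitution_effects_g.get(m)
            sub_s = f"{sub:>12.0f}" if sub is not None else f"{'--':>12}"
            lines.append(
                f"{m:<12}{self.codings[m].mode:<16}"
                f"{self.coefficients[m]:>12.4f}{self.coefficient_p[m]:>12.3g}{sub_s}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "members": self.members,
            "modes": {m: self.codings[m].mode for m in self.members},
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "coefficient_p": self.coefficient_p,
            "r2": self.r2,
            "aic": self.aic,
            "substitution_effects_g": self.substitution_effects_g,
        }


def substitution_effects(
    model: SnpNetworkModel, include_over_dominant: bool = False
) -> dict[str, float]:
    """Homozygote substitution effect per member locus, in grams.

    With other members held fixed, swapping ref-hom for alt-hom changes
    the coded predictor by ``codes[2] - codes[0]``, so the predicted trait
    change is ``coef * (codes[2] - codes[0])`` kg.  An additive locus with
    coefficient ``b`` therefore substitutes ``2000 b`` grams.
    """
    out = {}
    for m in model.members:
        codes = model.codings[m].codes
        gap = codes[2] - codes[0]
        if model.codings[m].mode == "over_dominant" and not include_over_dominant:
            continue
        out[m] = 1000.0 * model.coefficients[m] * gap
    return out


def code_genotypes(
    dosages: pd.DataFrame, codings: dict[str, ModeCoding]
) -> pd.DataFrame:
    """Apply each locus's mode coding to a dosage matrix (individuals x loci)."""
    coded = {}
    for locus, coding in codings.items():
        coded[locus] = coding.apply(dosages[locus].to_numpy())
    return pd.DataFrame(coded, index=dosages.index)


def _stepwise_select(
    coded: pd.DataFrame, y: np.ndarray, direction: str, alpha: float
) -> list[str]:
    candidates = list(coded.columns)
    if direction == "forward":
        current: list[str] = []
        while True:
            best = None
            for c in candidates:
                if c in current:
                    continue
                fit = _ols(coded[current + [c]].to_numpy(float), y)
                if fit["singular"]:
                    continue
                p_c = fit["p"][-1]
                if best is None or p_c < best[0]:
                    best = (p_c, c)
            if best is None or best[0] >= alpha:
                break
            current.append(best[1])
            # stay check: drop members that lost significance
            while True:
                fit = _ols(coded[current].to_numpy(float), y)
                worst = max(range(len(current)), key=lambda i: fit["p"][i + 1])
                if fit["p"][worst + 1] >= alpha and len(current) > 1:
                    current.pop(worst)
                else:
                    break
        return current
    if direction == "backward":
        current = list(candidates)
        while current:
            fit = _ols(coded[current].to_numpy(float), y)
            if fit["singular"]:
                dropped = current.pop()  # later-entering locus leaves first
                warnings.warn(f"collinear coding, dropping {dropped}", stacklevel=2)
                continue
            worst = max(range(len(current)), key=lambda i: fit["p"][i + 1])
            if fit["p"][worst + 1] >= alpha:
                current.pop(worst)
            else:
                break
        return current
    raise ValueError("direction must be 'forward' or 'backward'")


def stepwise_network_search(
    dosages: pd.DataFrame,
    mw,
    candidate_loci: list[str] | None = None,
    direction: str = "forward",
    alpha: float = 0.05,
    max_size: int = 4,
    min_size: int = 2,
    max_survivors: int = 12,
) -> list[SnpNetworkModel]:
    """Enumerate SNP networks surviving stepwise selection, ranked by AIC.

    Each candidate locus first gets its AIC-best single-SNP mode coding;
    loci whose single-SNP association reaches ``p < alpha`` enter the
    stepwise search (entry and stay threshold ``alpha`` on partial
    F-tests).  All subsets of the surviving set with ``min_size`` to
    ``max_size`` members whose coefficients all remain significant
    jointly are returned as fitted :class:`SnpNetworkModel` objects,
    sorted by AIC.
    """
    y = np.asarray(mw, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    dosages = dosages.loc[keep] if keep.sum() != len(keep) else dosages
    loci = candidate_loci if candidate_loci is not None else list(dosages.columns)

    codings: dict[str, ModeCoding] = {}
    screened: list[str] = []
    for locus in loci:
        try:
            coding, fit = fit_single_snp_modes(dosages[locus], y, locus)
        except ValueError:
            continue
        codings[locus] = coding
        if fit["p"][1] < alpha:
            screened.append(locus)
    if not screened:
        return []
    coded = code_genotypes(dosages[screened], {l: codings[l] for l in screened})
    surviving = _stepwise_select(coded, y, direction, alpha)
    if len(surviving) > max_survivors:
        # subset enumeration is combinatorial; keep the strongest joint
        # predictors (large stepwise-surviving sets indicate overfitting)
        fit = _ols(coded[surviving].to_numpy(float), y)
        order = np.argsort(fit["p"][1:])[:max_survivors]
        kept = [surviving[i] for i in sorted(order)]
        warnings.warn(
            f"{len(surviving)} loci survived stepwise selection; "
            f"enumerating networks over the {max_survivors} strongest",
            stacklevel=2,
        )
        surviving = kept

    networks: list[SnpNetworkModel] = []
    for size in range(min_size, min(max_size, len(surviving)) + 1):
        for subset in itertools.combinations(surviving, size):
            X = coded[list(subset)].to_numpy(float)
            fit = _ols(X, y)
            if fit["singular"] or np.any(fit["p"][1:] >= alpha):
                continue
            model = SnpNetworkModel(
                members=list(subset),
                codings={m: codings[m] for m in subset},
                intercept=float(fit["beta"][0]),
                coefficients={m: float(b) for m, b in zip(subset, fit["beta"][1:])},
                coefficient_p={m: float(p) for m, p in zip(subset, fit["p"][1:])},
                r2=fit["r2"],
                aic=fit["aic"],
                fitted=fit["fitted"],
                actual=y,
            )
            model.substitution_effects_g = substitution_effects(model)
            networks.append(model)
    networks.sort(key=lambda nw: nw.aic)
    return networks


def spearman_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlations plus a dendrogram display order.

    ``values`` holds numeric columns (coded genotypes and the trait).
    Constant columns get NaN correlations.  The display order comes from
    average-linkage hierarchical clustering of ``1 - |rho|`` (NaN treated
    as maximal distance).
    """
    if len(values) < 3:
        raise ValueError("need >= 3 individuals")
    cols = list(values.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = values.corr(method="spearman")
    # pandas leaves constant columns as NaN already; make that explicit
    for c in cols:
        if values[c].nunique() <= 1:
            rho.loc[c, :] = np.nan
            rho.loc[:, c] = np.nan
    if len(cols) > 2:
        dist = 1.0 - rho.abs().to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.nan_to_num(dist, nan=1.0)
        dist = (dist + dist.T) / 2.0
        order_idx = leaves_list(linkage(squareform(dist, checks=False), method="average"))
        order = [cols[i] for i in order_idx]
    else:
        order = cols
    return rho, order
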