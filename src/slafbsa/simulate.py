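"""Synthetic data generator for the whole SLAF-BSA study design.

Produces every input the downstream pipeline consumes:

* a nested paternal half-sib population (sires x dams x full-sib progeny)
  with biallelic genotypes transmitted Mendelianly from founders, a
  polygenic breeding value, optional major causal loci
  (additive / dominant / over-dominant), and marketing-weight phenotypes
  with a configured narrow-sense heritability;
* pooled base-depth tables for two extreme-EBV bulks, with Poisson total
  depth, multinomial base counts and a sequencing-error-driven Phred
  quality value;
* qPCR CT tables with technical-replicate structure for the relative
  expression stage.

The phenotype model is ``mw = mean + sex offset + sum of causal genotypic
values (centred) + polygenic BV + N(0, sigma2_E)`` where the polygenic
additive variance is ``h2 * sd^2`` minus the additive variance already
explained by causal loci, and ``sigma2_E = (1 - h2) * sd^2``.  Realised
heritability therefore matches the configured value in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bsa import BASES, LocusDepthRecord, q_score
from .config import SimulationConfig

#: quality value reported when the simulated error rate is (numerically) zero
_Q_CAP = 60.0

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: fraction of simulated substitutions that are transitions (ti/tv ~ 2.33)
_TI_FRACTION = 0.6996


def _genotypic_values(effect: float, mode: str) -> np.ndarray:
    """Raw genotypic values for alt-dosage {0, 1, 2} under a causal mode."""
    if mode == "additive":
        return np.array([0.0, effect, 2.0 * effect])
    if mode == "dominant":
        return np.array([0.0, 2.0 * effect, 2.0 * effect])
    if mode == "over_dominant":
        return np.array([0.0, effect, 0.0])
    raise ValueError(f"unknown causal mode {mode!r}")


def _average_effect(effect: float, mode: str, p: float) -> float:
    """Allele-substitution average effect alpha = a + d(1-2p).

    ``a`` and ``d`` are the half-range and mid-heterozygote deviation of
    the genotypic values; alpha drives the additive (breeding-value)
    content of a causal locus.
    """
    g = _genotypic_values(effect, mode)
    a = (g[2] - g[0]) / 2.0
    d = g[1] - (g[0] + g[2]) / 2.0
    return a + d * (1.0 - 2.0 * p)


@dataclass
class TruePopulation:
    """A simulated population with full truth attached.

    ``pedigree`` has one row per individual (founders first) with columns
    ``id, sire, dam, sex, mw, true_bv``; founder ``mw`` is NaN (only
    progeny are phenotyped).  ``genotypes`` is an (individuals x loci)
    alt-allele dosage matrix aligned with ``pedigree`` rows and the
    ``loci`` table (``locus_id, chrom, pos, ref, alt, founder_freq,
    is_causal, effect, mode``).
    """

    pedigree: pd.DataFrame
    genotypes: np.ndarray
    loci: pd.DataFrame
    config: SimulationConfig

    @property
    def progeny(self) -> pd.DataFrame:
        return self.pedigree[self.pedigree["mw"].notna()]

    def row_of(self, ids: Sequence[str]) -> np.ndarray:
        index = pd.Index(self.pedigree["id"])
        return index.get_indexer(ids)

    def genotype_strings(self) -> pd.DataFrame:
        """Genotypes as unordered allele pairs, individuals x loci."""
        ref = self.loci["ref"].to_numpy()
        alt = self.loci["alt"].to_numpy()
        strings = np.empty(self.genotypes.shape, dtype=object)
        for dosage in (0, 1, 2):
            mask = self.genotypes == dosage
            for j in np.flatnonzero(mask.any(axis=0)):
                pair = "".join(sorted(ref[j] * (2 - dosage) + alt[j] * dosage))
                strings[mask[:, j], j] = pair
        return pd.DataFrame(
            strings, index=self.pedigree["id"], columns=self.loci["locus_id"]
        )


def _draw_loci(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_loci
    width = len(str(n))
    locus_id = [f"L{i + 1:0{width}d}" for i in range(n)]
    n_chrom = min(10, n)
    chrom = [f"C{(i % n_chrom) + 1:02d}" for i in range(n)]
    pos = np.arange(n) // n_chrom * 1000 + 1
    ref = rng.choice(list(BASES), size=n)
    is_ti = rng.random(n) < _TI_FRACTION
    alt = np.empty(n, dtype=object)
    for i, r in enumerate(ref):
        if is_ti[i]:
            alt[i] = _TRANSITION_PARTNER[r]
        else:
            tv = [b for b in BASES if b != r and b != _TRANSITION_PARTNER[r]]
            alt[i] = tv[rng.integers(len(tv))]
    freq = rng.uniform(0.1, 0.9, size=n)
    is_causal = np.zeros(n, dtype=bool)
    effect = np.zeros(n)
    mode = np.array(["none"] * n, dtype=object)
    if config.n_causal:
        causal_idx = rng.choice(n, size=config.n_causal, replace=False)
        is_causal[causal_idx] = True
        effect[causal_idx] = config.causal_effect_sizes
        mode[causal_idx] = config.causal_modes
        if config.causal_founder_freq is not None:
            freq[causal_idx] = config.causal_founder_freq
    return pd.DataFrame(
        {
            "locus_id": locus_id,
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "founder_freq": freq,
            "is_causal": is_causal,
            "effect": effect,
            "mode": mode,
        }
    )


def _transmit(parent_dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per (individual, locus): allele ~ Bernoulli(dosage / 2)."""
    return rng.binomial(1, parent_dosage / 2.0)


def simulate_population(config: SimulationConfig) -> TruePopulation:
    """Simulate the nested half-sib population with phenotypes and truth.

    Deterministic for a fixed ``config.seed``.  Raises ``ValueError`` if
    the causal loci already explain more additive variance than
    ``heritability * trait_sd**2`` allows.
    """
    rng = np.random.default_rng(config.seed)
    loci = _draw_loci(config, rng)
    freqs = loci["founder_freq"].to_numpy()

    n_sires = config.n_sires
    n_dams = config.n_sires * config.dams_per_sire
    n_prog = config.n_progeny
    sire_ids = [f"S{i + 1:03d}" for i in range(n_sires)]
    dam_ids = [f"D{i + 1:04d}" for i in range(n_dams)]
    prog_ids = [f"P{i + 1:05d}" for i in range(n_prog)]

    # founder genotypes from Hardy-Weinberg at the founder frequency
    g_sire = rng.binomial(2, freqs, size=(n_sires, config.n_loci))
    g_dam = rng.binomial(2, freqs, size=(n_dams, config.n_loci))

    # mating design: dam d belongs to sire d // dams_per_sire;
    # progeny k comes from dam k // progeny_per_dam
    dam_sire = np.repeat(np.arange(n_sires), config.dams_per_sire)
    prog_dam = np.repeat(np.arange(n_dams), config.progeny_per_dam)
    prog_sire = dam_sire[prog_dam]
    g_prog = _transmit(g_sire[prog_sire], rng) + _transmit(g_dam[prog_dam], rng)

    # variance bookkeeping
    sigma2_p = config.trait_sd**2
    sigma2_a = config.heritability * sigma2_p
    sigma2_e = (1.0 - config.heritability) * sigma2_p
    causal = loci[loci["is_causal"]]
    va_causal = 0.0
    for _, row in causal.iterrows():
        p = row["founder_freq"]
        alpha = _average_effect(row["effect"], row["mode"], p)
        va_causal += 2.0 * p * (1.0 - p) * alpha**2
    sigma2_poly = sigma2_a - va_causal
    if sigma2_poly < -1e-12:
        raise ValueError(
            f"causal loci explain additive variance {va_causal:.4g} exceeding "
            f"h2 * trait_sd^2 = {sigma2_a:.4g}; reduce effects or raise trait_sd"
        )
    sigma2_poly = max(sigma2_poly, 0.0)
    sd_poly = np.sqrt(sigma2_poly)

    bv_sire = rng.normal(0.0, sd_poly, n_sires) if sd_poly > 0 else np.zeros(n_sires)
    bv_dam = rng.normal(0.0, sd_poly, n_dams) if sd_poly > 0 else np.zeros(n_dams)
    mendelian = (
        rng.normal(0.0, np.sqrt(sigma2_poly / 2.0), n_prog)
        if sigma2_poly > 0
        else np.zeros(n_prog)
    )
    bv_poly_prog = 0.5 * (bv_sire[prog_sire] + bv_dam[prog_dam]) + mendelian

    # causal contributions: raw genotypic value (centred) and BV content
    def causal_parts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        value = np.zeros(g.shape[0])
        bv = np.zeros(g.shape[0])
        for idx, row in causal.iterrows():
            j = loci.index.get_loc(idx)
            p = row["founder_freq"]
            gv = _genotypic_values(row["effect"], row["mode"])
            mean_gv = gv[0] * (1 - p) ** 2 + gv[1] * 2 * p * (1 - p) + gv[2] * p**2
            alpha = _average_effect(row["effect"], row["mode"], p)
            value += gv[g[:, j]] - mean_gv
            bv += alpha * (g[:, j] - 2.0 * p)
        return value, bv

    gval_prog, gbv_prog = causal_parts(g_prog)
    _, gbv_sire = causal_parts(g_sire)
    _, gbv_dam = causal_parts(g_dam)

    sex = np.where(rng.random(n_prog) < 0.5, "M", "F")
    env = (
        rng.normal(0.0, np.sqrt(sigma2_e), n_prog)
        if sigma2_e > 0
        else np.zeros(n_prog)
    )
    mw = (
        config.trait_mean
        + np.where(sex == "F", config.female_offset, 0.0)
        + gval_prog
        + bv_poly_prog
        + env
    )

    pedigree = pd.DataFrame(
        {
            "id": sire_ids + dam_ids + prog_ids,
            "sire": [""] * (n_sires + n_dams)
            + [sire_ids[s] for s in prog_sire],
            "dam": [""] * (n_sires + n_dams) + [dam_ids[d] for d in prog_dam],
            "sex": ["M"] * n_sires + ["F"] * n_dams + list(sex),
            "mw": [np.nan] * (n_sires + n_dams) + list(mw),
            "true_bv": np.concatenate(
                [bv_sire + gbv_sire, bv_dam + gbv_dam, bv_poly_prog + gbv_prog]
            ),
        }
    )
    genotypes = np.vstack([g_sire, g_dam, g_prog]).astype(np.int8)
    return TruePopulation(pedigree=pedigree, genotypes=genotypes, loci=loci, config=config)


def mendelian_violations(pop: TruePopulation) -> int:
    """Count progeny-locus pairs whose dosage is impossible given the parents.

    A parent of dosage 0/1/2 can transmit alleles {0}/{0,1}/{1}; a progeny
    dosage is consistent iff it equals some transmissible sire allele plus
    some transmissible dam allele.
    """
    ped = pop.pedigree
    idx = pd.Index(ped["id"])
    prog_mask = ped["sire"].ne("").to_numpy()
    rows = np.flatnonzero(prog_mask)
    sire_rows = idx.get_indexer(ped.loc[prog_mask, "sire"])
    dam_rows = idx.get_indexer(ped.loc[prog_mask, "dam"])
    g = pop.genotypes
    gp, gs, gd = g[rows], g[sire_rows], g[dam_rows]
    lo = (gs == 2).astype(int) + (gd == 2).astype(int)
    hi = 2 - (gs == 0).astype(int) - (gd == 0).astype(int)
    return int(np.sum((gp < lo) | (gp > hi)))


def simulate_bulk_depths(
    pop: TruePopulation,
    low_ids: Sequence[str],
    high_ids: Sequence[str],
    mean_depth: float,
    error_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Pooled base-depth table for the two extreme bulks.

    Per locus and bulk the total depth is Poisson(``mean_depth``) and the
    four base counts are multinomial around the bulk's true alt-allele
    frequency (alt-allele count over twice the bulk size), with
    ``error_rate`` probability of a read being miscalled uniformly to the
    other three bases.  The emitted quality value is
    ``-10 log10(error_rate)`` (capped at 60 when the error rate is 0).

    Returns the standard locus-depth table with columns
    ``locus_id, chrom, pos, ref, alt, A_H, C_H, G_H, T_H, A_L, C_L, G_L,
    T_L, Q``.
    """
    low_ids, high_ids = list(low_ids), list(high_ids)
    if not low_ids or not high_ids:
        raise ValueError("both bulks must be non-empty")
    if set(low_ids) & set(high_ids):
        raise ValueError("bulk id lists must be disjoint")
    rng = np.random.default_rng(seed)
    loci = pop.loci
    n = len(loci)
    ref_idx = loci["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    alt_idx = loci["alt"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    q = q_score(error_rate) if error_rate > 0 else _Q_CAP

    out = loci[["locus_id", "chrom", "pos", "ref", "alt"]].copy()
    for tag, ids in (("H", high_ids), ("L", low_ids)):
        rows = pop.row_of(ids)
        if np.any(rows < 0):
            raise KeyError(f"unknown individual ids in bulk {tag}")
        f_alt = pop.genotypes[rows].mean(axis=0) / 2.0
        p_true = np.zeros((n, 4))
        p_true[np.arange(n), ref_idx] = 1.0 - f_alt
        p_true[np.arange(n), alt_idx] += f_alt
        # miscalls move error_rate of each base's mass uniformly to the others
        p_obs = p_true * (1.0 - error_rate) + (1.0 - p_true) * (error_rate / 3.0)
        p_obs /= p_obs.sum(axis=1, keepdims=True)
        total = rng.poisson(mean_depth, size=n)
        counts = rng.multinomial(total, p_obs)
        for k, base in enumerate(BASES):
            out[f"{base}_{tag}"] = counts[:, k]
    out["Q"] = q
    return out


def depth_records(depths: pd.DataFrame) -> list[LocusDepthRecord]:
    """Convert a locus-depth table into `LocusDepthRecord` objects."""
    recs = []
    for row in depths.itertuples(index=False):
        recs.append(
            LocusDepthRecord(
                locus_id=row.locus_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                depth_h=(row.A_H, row.C_H, row.G_H, row.T_H),
                depth_l=(row.A_L, row.C_L, row.G_L, row.T_L),
                q_value=float(row.Q),
            )
        )
    return recs


def simulate_expression(
    groups: Sequence[str],
    fold_changes: Sequence[float],
    ct_noise_sd: float,
    n_per_group: int,
    seed: int,
    gene: str = "gene1",
    n_replicates: int = 3,
    reference_ct: float = 18.0,
    baseline_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """qPCR CT table for genotype groups with known true fold changes.

    Reference-gene CT is constant plus Gaussian noise; target CT is
    ``reference_ct + baseline_delta_ct - log2(fold_change) + noise``.  Each
    sample carries ``n_replicates`` technical replicates.
    """
    if len(groups) != len(fold_changes):
        raise ValueError("groups and fold_changes must align")
    fold_changes = np.asarray(fold_changes, dtype=float)
    if np.any(fold_changes <= 0):
        raise ValueError("fold changes must be > 0")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    sample_no = 0
    for group, fc in zip(groups, fold_changes):
        target_mean = reference_ct + baseline_delta_ct - np.log2(fc)
        for _ in range(n_per_group):
            sample_no += 1
            sid = f"sample{sample_no:03d}"
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": gene,
                        "genotype_group": group,
                        "replicate": rep,
                        "ct_target": target_mean + rng.normal(0.0, ct_noise_sd),
                        "ct_reference": reference_ct + rng.normal(0.0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)
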