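"""Per-locus pooled-bulk statistics for bulked segregant analysis.

Two DNA bulks — pooled from individuals with extreme high and extreme low
estimated breeding values (HEBV / LEBV) — are sequenced, and each SLAF locus
carries a per-bulk depth of the four bases.  This module computes the
per-locus statistics used to nominate trait-associated SNPs:

* the Phred sequencing quality value ``Q = -10 log10(p_err)``,
* the Euclidean distance (ED) between the two bulks' base-composition
  vectors (base depths are normalised to within-bulk fractions first, so
  ED lies in ``[0, sqrt(2)]``),
* the per-bulk SNP index ``M / (M + P)`` (alt-allele depth over focal-allele
  depth) and its between-bulk difference, the delta SNP index,
* the joint quality filter ``ED >= 0.7 and |delta SNP index| >= 0.5 and
  Q >= 30`` (all thresholds inclusive),
* transition/transversion accounting over the retained loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: unordered base pairs that are transitions (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})

#: default joint-filter thresholds, all inclusive
ED_MIN = 0.7
DELTA_MIN = 0.5
Q_MIN = 30.0


def q_score(p_err: float) -> float:
    """Phred quality value for a base-call error probability.

    ``Q = -10 * log10(p_err)``; an accuracy of 99.9% (``p_err = 0.001``)
    corresponds to Q30.
    """
    if not 0.0 < p_err <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p_err!r}")
    return -10.0 * math.log10(p_err)


@dataclass(frozen=True)
class LocusDepthRecord:
    """One SLAF locus: per-bulk A/C/G/T read depths and a quality value.

    ``depth_h`` / ``depth_l`` are 4-tuples of counts in A, C, G, T order for
    the high-EBV and low-EBV bulk respectively.
    """

    locus_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth_h: tuple[float, float, float, float]
    depth_l: tuple[float, float, float, float]
    q_value: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based (>= 1), got {self.pos}")
        if any(d < 0 for d in self.depth_h) or any(d < 0 for d in self.depth_l):
            raise ValueError(f"negative depth at locus {self.locus_id}")
        for base in (self.ref, self.alt):
            if base not in _BASE_INDEX:
                raise ValueError(f"invalid nucleotide {base!r} at {self.locus_id}")


@dataclass
class BsaScore:
    """Per-locus bulk-contrast statistics and filter outcome."""

    locus_id: str
    ed: float
    snp_index_h: float
    snp_index_l: float
    delta_snp_index: float
    m_h: float
    p_h: float
    m_l: float
    p_l: float
    passes_filter: bool


def compute_ed(rec: LocusDepthRecord) -> float:
    """Euclidean distance between the bulks' base-fraction vectors.

    Depths are normalised within each bulk, so the result is in
    ``[0, sqrt(2)]`` regardless of coverage.  Raises if either bulk has
    zero total depth (the locus is unobserved in that bulk).
    """
    h = np.asarray(rec.depth_h, dtype=float)
    l = np.asarray(rec.depth_l, dtype=float)
    th, tl = h.sum(), l.sum()
    if th <= 0 or tl <= 0:
        raise ValueError(f"zero total depth in a bulk at locus {rec.locus_id}")
    return float(np.linalg.norm(h / th - l / tl))


def compute_snp_index(rec: LocusDepthRecord) -> tuple[float, float, float]:
    """Per-bulk SNP index and its difference (HEBV minus LEBV).

    The SNP index of a bulk is ``M / (M + P)`` where M is the depth of the
    alternative allele and P the depth of the reference allele.  If a bulk
    has no reads on either focal base, all three values are NaN (the locus
    cannot enter delta-SNP-index filtering).
    """
    ir, ia = _BASE_INDEX[rec.ref], _BASE_INDEX[rec.alt]
    m_h, p_h = rec.depth_h[ia], rec.depth_h[ir]
    m_l, p_l = rec.depth_l[ia], rec.depth_l[ir]
    if (m_h + p_h) <= 0 or (m_l + p_l) <= 0:
        return (math.nan, math.nan, math.nan)
    idx_h = m_h / (m_h + p_h)
    idx_l = m_l / (m_l + p_l)
    return (idx_h, idx_l, idx_h - idx_l)


def score_locus(
    rec: LocusDepthRecord,
    ed_min: float = ED_MIN,
    delta_min: float = DELTA_MIN,
    q_min: float = Q_MIN,
) -> BsaScore:
    """Compute ED, SNP indices and the joint filter flag for one locus."""
    ed = compute_ed(rec)
    idx_h, idx_l, delta = compute_snp_index(rec)
    ir, ia = _BASE_INDEX[rec.ref], _BASE_INDEX[rec.alt]
    passes = (
        ed >= ed_min
        and not math.isnan(delta)
        and abs(delta) >= delta_min
        and rec.q_value >= q_min
    )
    return BsaScore(
        locus_id=rec.locus_id,
        ed=ed,
        snp_index_h=idx_h,
        snp_index_l=idx_l,
        delta_snp_index=delta,
        m_h=rec.depth_h[ia],
        p_h=rec.depth_h[ir],
        m_l=rec.depth_l[ia],
        p_l=rec.depth_l[ir],
        passes_filter=bool(passes),
    )


def filter_loci(
    scored: Iterable[tuple[LocusDepthRecord, BsaScore]],
) -> list[tuple[LocusDepthRecord, BsaScore]]:
    """Return the loci whose scores pass the joint filter, in input order."""
    return [(rec, sc) for rec, sc in scored if sc.passes_filter]


def score_table(
    depths: pd.DataFrame,
    ed_min: float = ED_MIN,
    delta_min: float = DELTA_MIN,
    q_min: float = Q_MIN,
) -> pd.DataFrame:
    """Vectorised scoring of a locus-depth table.

    ``depths`` must carry the columns produced by the simulator / readers:
    ``locus_id, chrom, pos, ref, alt, A_H..T_H, A_L..T_L, Q``.  Returns a
    copy with ``ed, snp_index_H, snp_index_L, delta_snp_index, m_H, p_H,
    m_L, p_L, passes_filter`` appended.  Loci with zero depth in a bulk get
    NaN statistics and fail the filter.
    """
    out = depths.copy()
    h = depths[[f"{b}_H" for b in BASES]].to_numpy(dtype=float)
    l = depths[[f"{b}_L" for b in BASES]].to_numpy(dtype=float)
    th = h.sum(axis=1)
    tl = l.sum(axis=1)
    ok = (th > 0) & (tl > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ed = np.linalg.norm(h / th[:, None] - l / tl[:, None], axis=1)
    ed[~ok] = np.nan

    ir = depths["ref"].map(_BASE_INDEX).to_numpy()
    ia = depths["alt"].map(_BASE_INDEX).to_numpy()
    rows = np.arange(len(depths))
    m_h, p_h = h[rows, ia], h[rows, ir]
    m_l, p_l = l[rows, ia], l[rows, ir]
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_h = np.where(m_h + p_h > 0, m_h / (m_h + p_h), np.nan)
        idx_l = np.where(m_l + p_l > 0, m_l / (m_l + p_l), np.nan)
    delta = idx_h - idx_l

    q = depths["Q"].to_numpy(dtype=float)
    passes = (
        (ed >= ed_min)
        & (np.abs(delta) >= delta_min)
        & (q >= q_min)
        & ~np.isnan(ed)
        & ~np.isnan(delta)
    )
    out["ed"] = ed
    out["snp_index_H"] = idx_h
    out["snp_index_L"] = idx_l
    out["delta_snp_index"] = delta
    out["m_H"], out["p_H"], out["m_L"], out["p_L"] = m_h, p_h, m_l, p_l
    out["passes_filter"] = passes
    return out


def is_transition(ref: str, alt: str) -> bool:
    """True for A<->G and C<->T substitutions, False for transversions."""
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    if ref not in _BASE_INDEX or alt not in _BASE_INDEX:
        raise ValueError(f"invalid nucleotides {ref!r}/{alt!r}")
    return frozenset((ref, alt)) in TRANSITIONS


def _class_label(pair: frozenset) -> str:
    a, b = sorted(pair)
    return f"{a}-{b}"


@dataclass
class SubstitutionSummary:
    """Counts/percentages per substitution class plus the ti/tv ratio.

    The six unordered classes are the two transitions (A-G, C-T) and the
    four transversions (A-C, A-T, C-G, G-T).  ``ti_tv_ratio`` is
    ``ti_percent / tv_percent`` (equivalently the count ratio).
    """

    counts: dict[str, int] = field(default_factory=dict)
    percents: dict[str, float] = field(default_factory=dict)
    ti_percent: float = math.nan
    tv_percent: float = math.nan
    ti_tv_ratio: float = math.nan

    @classmethod
    def from_class_percentages(cls, percents: dict[str, float]) -> "SubstitutionSummary":
        """Build a summary from externally reported per-class percentages."""
        ti = sum(v for k, v in percents.items() if frozenset(k.split("-")) in TRANSITIONS)
        tv = sum(v for k, v in percents.items() if frozenset(k.split("-")) not in TRANSITIONS)
        return cls(
            counts={},
            percents=dict(percents),
            ti_percent=ti,
            tv_percent=tv,
            ti_tv_ratio=ti / tv if tv > 0 else math.inf,
        )


def substitution_summary(loci: Sequence[tuple[str, str]]) -> SubstitutionSummary:
    """Classify (ref, alt) pairs into substitution classes.

    Returns per-class counts and percentages, the transition and
    transversion totals, and their ratio.
    """
    if not loci:
        raise ValueError("no loci to summarise")
    counts: dict[str, int] = {}
    n_ti = 0
    for ref, alt in loci:
        ti = is_transition(ref, alt)
        n_ti += ti
        label = _class_label(frozenset((ref, alt)))
        counts[label] = counts.get(label, 0) + 1
    n = len(loci)
    percents = {k: 100.0 * v / n for k, v in counts.items()}
    ti_pct = 100.0 * n_ti / n
    tv_pct = 100.0 - ti_pct
    ratio = ti_pct / tv_pct if tv_pct > 0 else math.inf
    return SubstitutionSummary(
        counts=counts,
        percents=percents,
        ti_percent=ti_pct,
        tv_percent=tv_pct,
        ti_tv_ratio=ratio,
    )
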