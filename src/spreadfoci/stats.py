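"""Strain-level statistics: summaries, tests, and the filament length model.

Covers four pieces of the analysis:

* per-strain focus count/length moments (sample SD, n−1 denominator);
* Wilcoxon rank-sum comparisons of focus-length samples (exact permutation
  enumeration for small samples, midrank/tie- and continuity-corrected
  normal approximation otherwise);
* spore-viability proportion tests: each dissected spore is treated as an
  independent Bernoulli trial and compared with a pooled two-proportion z
  test, with viable/total counts reconstructed from a (tetrads, % viable)
  table by inverting the rounding ("round-trip" rule);
* conversion of filament contour length in nm to nucleotides. RecA-family
  filaments stretch DNA ~1.5-fold, giving a rise of 0.34 × 1.5 = 0.51
  nm/nt; an additive offset (default 67.9 nm) absorbs the PSF- and
  antibody-decoration inflation of measured focus lengths and is calibrated
  so a 118.9 nm mean contour length maps to 100 nt.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from spreadfoci.detect import FocusRecord

__all__ = [
    "ChannelSummary", "StrainSummary", "ViabilityRecord", "TestResult",
    "ConversionParams", "summarize_strain", "wilcoxon_rank_sum",
    "viability_to_counts", "two_proportion_z", "nm_to_nucleotides",
    "load_viability_table",
]

#: Largest number of rank assignments enumerated by the exact Wilcoxon path.
_EXACT_ENUM_LIMIT = 400_000


@dataclass(frozen=True)
class ChannelSummary:
    channel: str
    n_foci: int
    count_mean: float
    count_sd: Optional[float]  # None when only one nucleus
    length_mean_nm: Optional[float]
    length_sd_nm: Optional[float]


@dataclass(frozen=True)
class StrainSummary:
    strain: str
    n_nuclei: int
    channels: tuple[ChannelSummary, ...]
    coloc_length_mean_nm: Optional[float] = None
    coloc_length_sd_nm: Optional[float] = None

    def channel(self, name: str) -> ChannelSummary:
        for c in self.channels:
            if c.channel == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class ViabilityRecord:
    """One spore-viability table row: tetrads dissected and % viable."""

    strain: str
    n_tetrads: int
    viability_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.viability_pct <= 100.0:
            raise ValueError("viability_pct must be in [0, 100]")
        if self.n_tetrads <= 0:
            raise ValueError("n_tetrads must be positive")

    @property
    def total_spores(self) -> int:
        return 4 * self.n_tetrads


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    alternative: str
    n1: int
    n2: int


@dataclass(frozen=True)
class ConversionParams:
    """Affine filament nm→nt model: nt = (L − offset) / rise."""

    rise_nm_per_nt: float = 0.51  # 0.34 nm B-DNA rise x 1.5 filament stretch
    offset_nm: float = 67.9  # calibrated: 118.9 nm contour <-> 100 nt

    def __post_init__(self) -> None:
        if self.rise_nm_per_nt <= 0:
            raise ValueError("rise must be positive")
        if self.offset_nm < 0:
            raise ValueError("offset must be >= 0")


def summarize_strain(
    fields: Sequence[Sequence[FocusRecord]],
    strain: str,
    coloc_lengths: Optional[Sequence[float]] = None,
) -> StrainSummary:
    """Per-strain moments: counts over nuclei, lengths pooled over foci.

    ``fields`` holds one record list per nucleus (both channels mixed).
    Count moments are taken across nuclei (including zero counts for a
    channel absent from a nucleus); length moments pool all foci of a
    channel. SDs are sample SDs and are reported missing when n = 1.
    """
    if not fields:
        raise ValueError("summarize_strain requires at least one nucleus")
    channels = sorted({r.channel for field in fields for r in field})
    summaries = []
    for ch in channels:
        counts = np.array(
            [sum(r.channel == ch for r in field) for field in fields], dtype=float
        )
        lengths = np.array(
            [r.major_length_nm for field in fields for r in field if r.channel == ch]
        )
        summaries.append(
            ChannelSummary(
                channel=ch,
                n_foci=int(lengths.size),
                count_mean=float(counts.mean()),
                count_sd=float(counts.std(ddof=1)) if counts.size > 1 else None,
                length_mean_nm=float(lengths.mean()) if lengths.size else None,
                length_sd_nm=float(lengths.std(ddof=1)) if lengths.size > 1 else None,
            )
        )
    cl = np.asarray(coloc_lengths, dtype=float) if coloc_lengths is not None else None
    return StrainSummary(
        strain=strain,
        n_nuclei=len(fields),
        channels=tuple(summaries),
        coloc_length_mean_nm=float(cl.mean()) if cl is not None and cl.size else None,
        coloc_length_sd_nm=(
            float(cl.std(ddof=1)) if cl is not None and cl.size > 1 else None
        ),
    )


def _wilcoxon_exact(ranks: np.ndarray, n1: int, w_obs: float, alternative: str):
    """Exact conditional permutation distribution of the rank sum of sample
    1 over all C(n, n1) assignments of the observed (mid)ranks."""
    idx = range(ranks.size)
    tol = 1e-9
    n_le = n_ge = total = 0
    for comb in combinations(idx, n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + tol:
            n_le += 1
        if w >= w_obs - tol:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test for two independent samples.

    The statistic is the rank sum of ``x`` in the combined sample with
    midranks for ties. For ``min(n1, n2) <= 8`` (and a feasible number of
    rank assignments) the p-value is exact by enumeration of the
    conditional permutation distribution; otherwise a normal approximation
    with tie correction and a 0.5 continuity correction is used.
    ``alternative`` is with respect to ``x`` ("less" = x tends smaller).
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())

    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult("wilcoxon_rank_sum", w, 1.0, alternative, n1, n2)

    if min(n1, n2) <= 8 and math.comb(n, min(n1, n2)) <= _EXACT_ENUM_LIMIT:
        p = _wilcoxon_exact(ranks, n1, w, alternative)
        return TestResult("wilcoxon_rank_sum", w, float(p), alternative, n1, n2)

    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult("wilcoxon_rank_sum", w, 1.0, alternative, n1, n2)
    sd = math.sqrt(var)
    p_less = float(norm.cdf((w - mean + 0.5) / sd))
    p_greater = float(norm.sf((w - mean - 0.5) / sd))
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return TestResult("wilcoxon_rank_sum", w, p, alternative, n1, n2)


def viability_to_counts(
    record: ViabilityRecord, strict: bool = True
) -> tuple[int, int]:
    """Reconstruct (viable_spores, total_spores) from a viability row.

    Total spores is 4 per dissected tetrad; the viable count is the unique
    integer k with ``round(100·k/total, 1) = viability_pct`` (half-up
    rounding, checked with exact integer arithmetic). If no such k exists
    the printed percentage cannot come from ``4·n_tetrads`` spores — the
    strain's dissections did not all yield four spores — and an
    inconsistent-row error names the strain. ``strict=False`` instead falls
    back to the nearest count, for exploratory comparisons only.
    """
    total = record.total_spores
    p10 = round(record.viability_pct * 10)
    # round(100 k / total, 1) == pct  <=>  (2 p10 - 1) total <= 2000 k < (2 p10 + 1) total
    lo = (2 * p10 - 1) * total
    hi = (2 * p10 + 1) * total
    ks = [k for k in range(total + 1) if lo <= 2000 * k < hi]
    if len(ks) == 1:
        return ks[0], total
    if not strict:
        k = int(round(record.viability_pct / 100.0 * total))
        return min(k, total), total
    if not ks:
        raise ValueError(
            f"inconsistent row for strain {record.strain!r}: no viable-spore "
            f"count in 0..{total} rounds to {record.viability_pct}% — not all "
            "tetrads can have yielded 4 dissected spores"
        )
    raise ValueError(
        f"ambiguous row for strain {record.strain!r}: counts {ks} all round "
        f"to {record.viability_pct}%"
    )


def two_proportion_z(
    viable1: int,
    total1: int,
    viable2: int,
    total2: int,
    alternative: str = "two-sided",
) -> TestResult:
    """Pooled two-proportion z test.

    ``z = (p1 − p2) / sqrt(p̂(1−p̂)(1/n1 + 1/n2))`` with p̂ the pooled
    proportion; the squared statistic equals the 2×2 chi-square statistic
    without continuity correction. A degenerate pooled proportion of 0 or 1
    (equal sample proportions) gives z = 0, p = 1.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if total1 <= 0 or total2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= viable1 <= total1 and 0 <= viable2 <= total2):
        raise ValueError("counts must lie in [0, total]")
    p1, p2 = viable1 / total1, viable2 / total2
    pooled = (viable1 + viable2) / (total1 + total2)
    var = pooled * (1.0 - pooled) * (1.0 / total1 + 1.0 / total2)
    if var == 0.0:
        return TestResult("two_proportion_z", 0.0, 1.0, alternative, total1, total2)
    z = (p1 - p2) / math.sqrt(var)
    if alternative == "less":
        p = float(norm.cdf(z))
    elif alternative == "greater":
        p = float(norm.sf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return TestResult("two_proportion_z", float(z), p, alternative, total1, total2)


def nm_to_nucleotides(
    length_nm: float, params: ConversionParams = ConversionParams()
) -> float:
    """Convert a filament contour length in nm to nucleotides.

    ``nt = (length − offset) / rise``; lengths at or below the offset (all
    PSF/decoration, no resolvable filament) return 0 with a warning.
    """
    if length_nm < 0:
        raise ValueError("length_nm must be >= 0")
    if length_nm < params.offset_nm:
        warnings.warn(
            f"contour length {length_nm} nm is below the {params.offset_nm} nm "
            "offset; returning 0 nucleotides",
            stacklevel=2,
        )
        return 0.0
    return (length_nm - params.offset_nm) / params.rise_nm_per_nt


def load_viability_table(path=None) -> pd.DataFrame:
    """Spore-viability table (packaged fixture by default).

    Columns: strain, n_tetrads, viability_pct, comparison, censored.
    Rows whose printed viability is a bound (e.g. "<0.6") or whose tetrad
    count is non-numeric are marked ``censored`` and carry NaN values.
    """
    if path is None:
        src = resources.files("spreadfoci").joinpath("data/table1_viability.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"strain", "n_tetrads", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    pct = pd.to_numeric(df["viability_pct"], errors="coerce")
    n = pd.to_numeric(df["n_tetrads"], errors="coerce")
    df = df.assign(
        n_tetrads=n, viability_pct=pct, censored=pct.isna() | n.isna()
    )
    if "comparison" not in df.columns:
        df["comparison"] = ""
    return df
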