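"""Per-genome Csp distribution and nonparametric group comparison.

Genomes carrying cold-shock proteins are split into a low group (one or
two Csps) and a high group (three or more, by default), and genome size
and GC content are compared between the groups with a two-sided
Mann-Whitney U test. The comparison is always nonparametric here: the
group features are skewed in real data, and the rank test is the terminal
choice; normality screening is deliberately not part of the pipeline.

The U statistic is ``min(U_x, U_y)`` from midrank sums. The p-value is
exact (full enumeration of label arrangements) when the smaller sample
has at most 8 observations and there are no ties; otherwise a normal
approximation with tie-corrected variance and continuity correction is
used.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

EXACT_MAX_N = 8  # enumeration stays within C(16, 8) arrangements


class GenomeDataError(ValueError):
    pass


class SampleSizeError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    size: int
    gc: float
    csp_ids: tuple[str, ...]
    taxon: str = ""

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise GenomeDataError(f"{self.genome_id}: genome size must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise GenomeDataError(f"{self.genome_id}: GC must lie in [0, 1]")
        if len(set(self.csp_ids)) != len(self.csp_ids):
            raise GenomeDataError(f"{self.genome_id}: duplicate csp ids")

    @property
    def csp_count(self) -> int:
        return len(self.csp_ids)


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise GenomeDataError("no countable A/C/G/T bases")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise GenomeDataError(f"unexpected characters in nucleotide sequence: {sorted(bad)}")
    return (counts["G"] + counts["C"]) / denom


def split_by_csp_count(
    genomes: Iterable[GenomeRecord], threshold: int = 3
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Partition into (count < threshold, count >= threshold).

    Genomes with zero Csps are outside the study universe and are dropped
    with a warning.
    """
    import warnings

    low: list[GenomeRecord] = []
    high: list[GenomeRecord] = []
    for g in genomes:
        if g.csp_count == 0:
            warnings.warn(
                f"genome {g.genome_id} has no Csps and is excluded", stacklevel=2
            )
            continue
        (high if g.csp_count >= threshold else low).append(g)
    return low, high


def _u_statistics(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(U_x, U_y) from midrank sums; U_x + U_y = n*m."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2
    return u_x, n * m - u_x


def _exact_p(x: Sequence[float], y: Sequence[float], u_obs: float) -> float:
    """Two-sided exact p by full enumeration of label arrangements.

    Tie-free ranks are a permutation of 1..n+m, so U_x depends only on which
    rank positions x occupies; the null distribution of U_x is symmetric
    about nm/2, making the two-sided p twice the lower tail at min(U_x, U_y).
    """
    n, m = len(x), len(y)
    total = n + m
    count_le = 0
    n_arr = 0
    for positions in combinations(range(total), n):
        rank_sum = sum(p + 1 for p in positions)
        u_x = rank_sum - n * (n + 1) / 2
        n_arr += 1
        if u_x <= u_obs + 1e-12:
            count_le += 1
    return min(2.0 * count_le / n_arr, 1.0)


def _approx_p(x: Sequence[float], y: Sequence[float], u_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction, applied to U = min(U_x, U_y)."""
    n, m = len(x), len(y)
    total = n + m
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    mu = n * m / 2.0
    var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var <= 0:
        return 1.0
    z = (u_obs - mu + 0.5) / math.sqrt(var)
    from scipy.stats import norm

    p = 2.0 * norm.cdf(z)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    ``mode`` is ``exact`` (full enumeration; requires no ties), ``approx``
    (tie-corrected normal approximation with continuity correction) or
    ``auto`` (exact when min(n, m) <= 8 and there are no ties).
    """
    if len(x) == 0 or len(y) == 0:
        raise SampleSizeError("both samples must be nonempty")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError("mode must be 'exact', 'approx' or 'auto'")
    u_x, u_y = _u_statistics(x, y)
    u = min(u_x, u_y)
    pooled = list(x) + list(y)
    has_ties = len(set(pooled)) != len(pooled)
    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free samples")
    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and min(len(x), len(y)) <= EXACT_MAX_N
    )
    p = _exact_p(x, y, u) if use_exact else _approx_p(x, y, u)
    return u, p


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "median": float(med),
        "iqr": [float(q1), float(q3)],
        "mean": float(values.mean()),
    }


def compare_groups(
    genomes: Iterable[GenomeRecord],
    feature: str = "size",
    threshold: int = 3,
    mode: str = "auto",
) -> dict:
    """Compare a genome feature between the low- and high-Csp-count groups.

    Returns a deterministic report with group summaries (median, IQR, mean),
    the U statistic, the two-sided p-value, and the direction of effect.
    When either group is empty the comparison is reported as not testable
    and no p-value is fabricated.
    """
    if feature not in ("size", "gc"):
        raise ValueError("feature must be 'size' or 'gc'")
    low, high = split_by_csp_count(genomes, threshold=threshold)
    report: dict = {
        "feature": feature,
        "threshold": threshold,
        "testable": bool(low) and bool(high),
    }
    getter = (lambda g: float(g.size)) if feature == "size" else (lambda g: g.gc)
    if low:
        report["low"] = _summary(np.array([getter(g) for g in low]))
    if high:
        report["high"] = _summary(np.array([getter(g) for g in high]))
    if not report["testable"]:
        report["note"] = "one group is empty; comparison not testable"
        return report
    x = [getter(g) for g in low]
    y = [getter(g) for g in high]
    u, p = mann_whitney_u(x, y, mode=mode)
    report["U"] = float(u)
    report["p_two_sided"] = float(p)
    med_low, med_high = report["low"]["median"], report["high"]["median"]
    report["direction"] = (
        "high_group_larger"
        if med_high > med_low
        else "low_group_larger"
        if med_low > med_high
        else "equal_medians"
    )
    return report


def read_genomes_tsv(path: str | Path) -> list[GenomeRecord]:
    """Genome table: genome_id, size_bp, gc, taxon, csp_ids (comma-separated)."""
    out: list[GenomeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            csp_ids = tuple(t for t in row["csp_ids"].split(",") if t)
            out.append(
                GenomeRecord(
                    genome_id=row["genome_id"],
                    size=int(row["size_bp"]),
                    gc=float(row["gc"]),
                    taxon=row.get("taxon", ""),
                    csp_ids=csp_ids,
                )
            )
    return out


def write_genomes_tsv(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["genome_id", "size_bp", "gc", "taxon", "csp_ids"])
        for g in genomes:
            writer.writerow([g.genome_id, g.size, f"{g.gc:.6f}", g.taxon, ",".join(g.csp_ids)])
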