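"""Band-quantitation arithmetic: relative levels, specificity score,
readthrough fraction and pull-down enrichment.

A quantitation table holds one band intensity per (sample, probe,
replicate, fraction). The *specificity score* of a sample is its relative
efficiency for the baxL probe (RNA level relative to the CspD reference)
minus its relative efficiency for the gdx probe (level relative to the
CspA reference); positive scores indicate CspD-like target preference,
negative scores CspA-like. Scores are computed per replicate and then
aggregated as mean and sample standard deviation, so replicate error
propagates into the reported dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

QUANT_COLUMNS = ["sample", "probe", "replicate", "intensity", "fraction"]
FRACTIONS = ("total", "crude", "bound")


class QuantError(ValueError):
    pass


def validate_quant_table(q: pd.DataFrame) -> pd.DataFrame:
    """Check schema, nonnegative intensities and key uniqueness."""
    missing = [c for c in QUANT_COLUMNS if c not in q.columns]
    if missing:
        raise QuantError(f"quant table missing columns {missing}")
    if (q["intensity"] < 0).any():
        raise QuantError("band intensities must be nonnegative")
    bad_frac = set(q["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise QuantError(f"unknown fractions {sorted(bad_frac)}")
    key = q[["sample", "probe", "replicate", "fraction"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise QuantError(f"duplicate quantitation key {dup}")
    return q


def read_quant_tsv(path: str | Path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t")
    return validate_quant_table(q)


def relative_levels(
    q: pd.DataFrame,
    probe: str,
    reference_sample: str,
    normalize_by: Optional[str] = None,
    fraction: str = "total",
) -> dict[str, dict[int, float]]:
    """Per-replicate RNA level of every sample relative to a reference lane.

    Each replicate's intensity is divided by the reference sample's intensity
    in the same replicate, so the reference maps to 1.0 in every replicate.
    ``normalize_by`` optionally pre-divides every lane by a loading-control
    probe (e.g. tmRNA) before the reference division.
    """
    validate_quant_table(q)
    sub = q[(q["probe"] == probe) & (q["fraction"] == fraction)]
    if sub.empty:
        raise QuantError(f"no rows for probe {probe!r} in fraction {fraction!r}")

    def lane(sample: str, rep: int, use_probe: str) -> float:
        rows = q[
            (q["sample"] == sample)
            & (q["probe"] == use_probe)
            & (q["replicate"] == rep)
            & (q["fraction"] == fraction)
        ]
        if rows.empty:
            raise QuantError(
                f"missing lane: sample={sample!r} probe={use_probe!r} replicate={rep}"
            )
        return float(rows["intensity"].iloc[0])

    reps = sorted(sub["replicate"].unique())
    ref_levels: dict[int, float] = {}
    for rep in reps:
        v = lane(reference_sample, rep, probe)
        if normalize_by is not None:
            ctrl = lane(reference_sample, rep, normalize_by)
            if ctrl == 0:
                raise QuantError(
                    f"zero loading control for reference lane replicate {rep}"
                )
            v /= ctrl
        if v == 0:
            raise QuantError(
                f"zero reference intensity: sample={reference_sample!r} "
                f"probe={probe!r} replicate={rep}"
            )
        ref_levels[rep] = v

    out: dict[str, dict[int, float]] = {}
    for sample in sub["sample"].unique():
        per_rep: dict[int, float] = {}
        for rep in sorted(sub[sub["sample"] == sample]["replicate"].unique()):
            v = lane(sample, rep, probe)
            if normalize_by is not None:
                ctrl = lane(sample, rep, normalize_by)
                if ctrl == 0:
                    raise QuantError(
                        f"zero loading control: sample={sample!r} replicate={rep}"
                    )
                v /= ctrl
            per_rep[rep] = v / ref_levels[rep]
        out[sample] = per_rep
    return out


@dataclass(frozen=True)
class SpecificityResult:
    sample: str
    rel_baxL: tuple[float, ...]
    rel_gdx: tuple[float, ...]
    scores: tuple[float, ...]

    @property
    def score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def score_sd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0


def specificity_score(
    rel_baxL: Mapping[int, float], rel_gdx: Mapping[int, float], sample: str = ""
) -> SpecificityResult:
    """Per-replicate (relative efficiency for baxL) - (relative efficiency
    for gdx), aggregated as mean +/- sample SD over replicates."""
    if set(rel_baxL) != set(rel_gdx):
        raise QuantError(
            f"replicate mismatch for sample {sample!r}: "
            f"{sorted(rel_baxL)} vs {sorted(rel_gdx)}"
        )
    reps = sorted(rel_baxL)
    bax = tuple(rel_baxL[r] for r in reps)
    gdx = tuple(rel_gdx[r] for r in reps)
    return SpecificityResult(
        sample=sample,
        rel_baxL=bax,
        rel_gdx=gdx,
        scores=tuple(b - g for b, g in zip(bax, gdx)),
    )


def specificity_table(
    q: pd.DataFrame,
    baxl_probe: str = "baxL",
    gdx_probe: str = "gdx",
    baxl_reference: str = "CspD",
    gdx_reference: str = "CspA",
    normalize_by: Optional[str] = None,
) -> list[SpecificityResult]:
    """Specificity scores for every sample in a quantitation table."""
    rel_b = relative_levels(q, baxl_probe, baxl_reference, normalize_by=normalize_by)
    rel_g = relative_levels(q, gdx_probe, gdx_reference, normalize_by=normalize_by)
    samples = sorted(set(rel_b) & set(rel_g))
    return [specificity_score(rel_b[s], rel_g[s], sample=s) for s in samples]


def readthrough_fraction(terminated: float, readthrough: float) -> float:
    """Percentage of readthrough transcript relative to total: 100*RT/(T+RT)."""
    if terminated < 0 or readthrough < 0:
        raise QuantError("intensities must be nonnegative")
    total = terminated + readthrough
    if total == 0:
        raise QuantError("terminated + readthrough must be positive")
    return 100.0 * readthrough / total


def enrichment_ratio(
    q: pd.DataFrame,
    sample: str,
    components: Sequence[str],
    replicate: Optional[int] = None,
) -> float:
    """Pull-down enrichment: (sum of bound component bands) / (sum of crude
    component bands). ``components`` lists the probe bands to sum, e.g. the
    full-length and truncated species of one mRNA."""
    validate_quant_table(q)
    sums = {}
    for frac in ("bound", "crude"):
        sel = q[
            (q["sample"] == sample)
            & (q["fraction"] == frac)
            & (q["probe"].isin(list(components)))
        ]
        if replicate is not None:
            sel = sel[sel["replicate"] == replicate]
        found = set(sel["probe"])
        missing = set(components) - found
        if missing:
            raise QuantError(
                f"missing {frac} bands for sample {sample!r}: {sorted(missing)}"
            )
        sums[frac] = float(sel["intensity"].sum())
    if sums["crude"] == 0:
        raise QuantError(f"zero crude-extract signal for sample {sample!r}")
    return sums["bound"] / sums["crude"]
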