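"""Particle-attached vs free-living lifestyle classification.

The lifestyle odds ratio of an OTU is

    odds ratio = log10( RA_PA / RA_FL ),

the log10 ratio of its mean relative abundance in the particle-attached
(>3.0 µm) fraction to that in the free-living (0.22–3.0 µm) fraction.
A positive odds ratio marks PA preference, a negative one FL preference;
an OTU detected in exactly one fraction is "exclusive" to it (the ratio is
±∞ and is reported as an exclusive call rather than a number). OTUs whose
sign switches across pressure levels have a dual lifestyle.

Calls are made per pressure level on replicate-mean relative abundances,
restricted to OTUs above an abundance floor (default 1%) in at least one
fraction at that pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AbsentOtuError, PairingError
from .otu_table import RelativeAbundanceTable

__all__ = [
    "odds_ratio",
    "classify_lifestyles",
    "shared_otus",
    "LifestyleResult",
]

PA_SIDE = frozenset({"PA-preference", "exclusive-PA"})
FL_SIDE = frozenset({"FL-preference", "exclusive-FL"})


def odds_ratio(ra_pa: float, ra_fl: float) -> float:
    """log10(RA_PA / RA_FL); ±inf signals an exclusive lifestyle.

    Raises :class:`AbsentOtuError` when both abundances are zero.
    """
    if ra_pa < 0 or ra_fl < 0:
        raise ValueError("relative abundances must be non-negative")
    if ra_pa == 0 and ra_fl == 0:
        raise AbsentOtuError("OTU absent from both fractions")
    if ra_fl == 0:
        return math.inf  # exclusive-PA
    if ra_pa == 0:
        return -math.inf  # exclusive-FL
    return math.log10(ra_pa / ra_fl)


def _call(ra_pa: float, ra_fl: float) -> str:
    if ra_pa == 0 and ra_fl == 0:
        return "absent"
    if ra_fl == 0:
        return "exclusive-PA"
    if ra_pa == 0:
        return "exclusive-FL"
    r = odds_ratio(ra_pa, ra_fl)
    if r > 0:
        return "PA-preference"
    if r < 0:
        return "FL-preference"
    return "neutral"


def _overall(calls: list[str]) -> str:
    called = [c for c in calls if c not in ("absent", "neutral")]
    if not called:
        return "unclassified"
    pa = [c for c in called if c in PA_SIDE]
    fl = [c for c in called if c in FL_SIDE]
    if pa and fl:
        # dual requires an actual sign switch of the numeric ratio; mixed
        # patterns involving only exclusives on one side stay unclassified
        if "PA-preference" in called and "FL-preference" in called:
            return "dual"
        return "unclassified"
    if all(c.startswith("exclusive") for c in called):
        return "exclusive"
    return "consistent-PA" if pa else "consistent-FL"


@dataclass
class LifestyleResult:
    """Per-(OTU, pressure) records and per-OTU overall summaries."""

    records: pd.DataFrame  # otu_id, pressure, ra_pa, ra_fl, odds_ratio, call
    summary: pd.DataFrame  # otu_id, overall + one call column per pressure


def classify_lifestyles(table: RelativeAbundanceTable,
                        sample_meta: pd.DataFrame,
                        abundance_floor: float = 0.01,
                        pseudo_abundance: float = 0.0) -> LifestyleResult:
    """Classify every OTU's lifestyle per pressure and overall.

    Parameters
    ----------
    table
        Relative abundances with samples spanning paired PA/FL fractions.
    sample_meta
        Indexed by sample id with columns ``pressure`` and ``fraction``
        (values ``"PA"``/``"FL"``). Replicates of a (pressure, fraction)
        cell are averaged.
    abundance_floor
        An OTU is called at a pressure only when its replicate-mean
        relative abundance reaches the floor in at least one fraction there.
    pseudo_abundance
        Added to both fraction means before the ratio (sensitivity
        analysis); the default 0 keeps zeros as exclusive calls.

    Raises
    ------
    PairingError
        When some pressure level has samples from only one fraction.
    """
    meta = sample_meta.loc[table.sample_ids]
    pressures = sorted(meta["pressure"].unique(), key=str)
    records = []
    calls_by_otu: dict = {otu: {} for otu in table.otu_ids}
    for pressure in pressures:
        pa_ids = meta.index[(meta["pressure"] == pressure)
                            & (meta["fraction"] == "PA")]
        fl_ids = meta.index[(meta["pressure"] == pressure)
                            & (meta["fraction"] == "FL")]
        if len(pa_ids) == 0 or len(fl_ids) == 0:
            raise PairingError(
                f"pressure {pressure!r}: PA samples={len(pa_ids)}, "
                f"FL samples={len(fl_ids)}; need both fractions"
            )
        ra_pa = table.proportions[pa_ids].mean(axis=1)
        ra_fl = table.proportions[fl_ids].mean(axis=1)
        for otu in table.otu_ids:
            a, b = float(ra_pa[otu]), float(ra_fl[otu])
            if a > 0 or b > 0:
                a += pseudo_abundance
                b += pseudo_abundance
            if max(a, b) < abundance_floor:
                call = "absent"
                ratio = np.nan
            else:
                call = _call(a, b)
                ratio = (math.log10(a / b)
                         if a > 0 and b > 0 else np.nan)
            records.append({
                "otu_id": otu, "pressure": pressure,
                "ra_pa": a, "ra_fl": b,
                "odds_ratio": ratio, "call": call,
            })
            calls_by_otu[otu][pressure] = call
    rec_df = pd.DataFrame.from_records(records)
    summary = pd.DataFrame.from_dict(calls_by_otu, orient="index")
    summary.index.name = "otu_id"
    summary["overall"] = [
        _overall([calls_by_otu[otu][p] for p in pressures])
        for otu in summary.index
    ]
    return LifestyleResult(rec_df, summary)


def shared_otus(set_a, set_b) -> dict:
    """Venn counts between two OTU sets."""
    a, b = set(set_a), set(set_b)
    return {
        "only_a": len(a - b),
        "only_b": len(b - a),
        "shared": len(a & b),
    }
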