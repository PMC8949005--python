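"""DNA stable-isotope-probing gradient processing.

A SIP incubation separates DNA on a CsCl buoyant-density gradient; taxa
that incorporated the ¹³C-labeled substrate carry heavier DNA and migrate
toward denser fractions. This module converts refractometer readings to
buoyant density, selects and pools "heavy" fractions from a gradient
profile, and calls incorporators ("active" OTUs) by the ≥1 percentage-point
rule: an OTU is active when its relative abundance in the ¹³C heavy
fraction exceeds that in the ¹²C heavy fraction by at least δ* (default
0.01).

The heavy-density window is a required, logged analysis choice; the
default [1.730, 1.746] g/mL follows common full-labeling SIP practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import NoHeavyFractionError, ScaleError

logger = logging.getLogger(__name__)

__all__ = [
    "DENSITY_COEFFS",
    "DEFAULT_HEAVY_WINDOW",
    "Fraction",
    "GradientProfile",
    "refractive_index_to_density",
    "density_to_refractive_index",
    "select_heavy_fractions",
    "pool_fractions",
    "identify_active_otus",
    "write_gradient_profiles",
    "read_gradient_profiles",
]

#: Empirical quadratic ρ(x) = c0 + c1·x + c2·x² converting refractive
#: index to CsCl buoyant density (g/mL).
DENSITY_COEFFS = (-75.9318, 99.2031, -31.2551)

#: Default heavy-fraction buoyant-density window (g/mL).
DEFAULT_HEAVY_WINDOW = (1.730, 1.746)

_SUM_TOL = 1e-6


def refractive_index_to_density(x, valid_range=(1.33, 1.46)):
    """Buoyant density ρ (g/mL) from refractive index x.

    Evaluates the empirical quadratic exactly; values of ``x`` outside
    ``valid_range`` (the plausible refractometer range) raise, guarding
    against unit mistakes. Accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    lo, hi = valid_range
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(
            f"refractive index outside [{lo}, {hi}]: {arr[(arr < lo) | (arr > hi)]}"
        )
    c0, c1, c2 = DENSITY_COEFFS
    rho = c0 + c1 * arr + c2 * arr ** 2
    return float(rho) if np.isscalar(x) else rho


def density_to_refractive_index(rho: float, valid_range=(1.33, 1.46)) -> float:
    """Numerically invert the density quadratic (monotone on the range)."""
    lo, hi = valid_range
    return brentq(lambda x: refractive_index_to_density(x, valid_range) - rho,
                  lo, hi, xtol=1e-12)


@dataclass
class Fraction:
    """One density-gradient fraction of a SIP incubation."""

    fraction_index: int
    refractive_index: float
    buoyant_density: float
    abundances: pd.Series  # otu_id -> relative abundance within fraction
    copy_number: float | None = None  # 16S copies/µL from qPCR, if measured


@dataclass
class GradientProfile:
    """Ordered fractions of one SIP incubation, bottom (densest) to top."""

    incubation_id: str
    label: str  # "13C" or "12C"
    fractions: list[Fraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("13C", "12C"):
            raise ValueError(f"label must be 13C or 12C, got {self.label!r}")
        dens = [f.buoyant_density for f in self.fractions]
        if any(b >= a for a, b in zip(dens, dens[1:])):
            raise ValueError(
                "buoyant density must strictly decrease bottom to top")
        for f in self.fractions:
            s = float(f.abundances.sum())
            if f.abundances.size and abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"fraction {f.fraction_index}: abundances sum to {s}")

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.buoyant_density for f in self.fractions])


def select_heavy_fractions(profile: GradientProfile,
                           window=DEFAULT_HEAVY_WINDOW) -> GradientProfile:
    """Subset of fractions whose buoyant density lies in ``window``.

    Raises :class:`NoHeavyFractionError` (listing available densities) when
    the window selects nothing.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window must satisfy lo < hi, got {window}")
    picked = [f for f in profile.fractions if lo <= f.buoyant_density <= hi]
    if not picked:
        raise NoHeavyFractionError(
            f"no fraction in density window [{lo}, {hi}]; available: "
            f"{np.round(profile.densities, 4).tolist()}"
        )
    logger.info("heavy window [%.3f, %.3f] g/mL selected fractions %s of %s/%s",
                lo, hi, [f.fraction_index for f in picked],
                profile.incubation_id, profile.label)
    return GradientProfile(profile.incubation_id, profile.label, picked)


def pool_fractions(profile: GradientProfile) -> pd.Series:
    """Combine fraction abundance vectors into one relative-abundance vector.

    Weighted mean across fractions; weights are qPCR copy numbers when every
    selected fraction has one (fractions differ in DNA mass), otherwise
    equal. A weighted mean of vectors that each sum to 1 again sums to 1.
    """
    if not profile.fractions:
        raise NoHeavyFractionError("cannot pool an empty profile")
    have_copies = all(f.copy_number is not None for f in profile.fractions)
    weights = np.array(
        [f.copy_number if have_copies else 1.0 for f in profile.fractions],
        dtype=float,
    )
    weights = weights / weights.sum()
    combined = None
    for w, f in zip(weights, profile.fractions):
        term = f.abundances * w
        combined = term if combined is None else combined.add(term, fill_value=0.0)
    return combined


def write_gradient_profiles(profiles, path) -> None:
    """Write profiles as long-format TSV (one row per fraction × OTU)."""
    rows = []
    for prof in profiles:
        for f in prof.fractions:
            for otu, ab in f.abundances.items():
                rows.append({
                    "incubation": prof.incubation_id, "label": prof.label,
                    "fraction": f.fraction_index,
                    "refractive_index": f.refractive_index,
                    "buoyant_density": f.buoyant_density,
                    "copy_number": f.copy_number,
                    "otu_id": otu, "abundance": ab,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gradient_profiles(path) -> list:
    """Read profiles written by :func:`write_gradient_profiles`."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (inc, label), sub in df.groupby(["incubation", "label"], sort=False):
        fractions = []
        for fi, fsub in sub.groupby("fraction", sort=True):
            first = fsub.iloc[0]
            copy = first["copy_number"]
            fractions.append(Fraction(
                fraction_index=int(fi),
                refractive_index=float(first["refractive_index"]),
                buoyant_density=float(first["buoyant_density"]),
                abundances=pd.Series(
                    fsub["abundance"].to_numpy(),
                    index=fsub["otu_id"].to_numpy()),
                copy_number=None if pd.isna(copy) else float(copy),
            ))
        fractions.sort(key=lambda f: -f.buoyant_density)
        profiles.append(GradientProfile(str(inc), str(label), fractions))
    return profiles


def identify_active_otus(heavy_13c: pd.Series, heavy_12c: pd.Series,
                         delta_star: float = 0.01) -> pd.DataFrame:
    """Call incorporators from pooled heavy-fraction abundance vectors.

    delta = RA(¹³C heavy) − RA(¹²C heavy) per OTU (an OTU missing from one
    input counts as 0 there); ``active`` ⇔ delta ≥ δ*. Output is sorted by
    delta descending, ties broken by OTU id for determinism.

    Raises :class:`ScaleError` when either input does not sum to 1 within
    1e-6 (guards against passing raw counts).
    """
    for name, vec in (("13C", heavy_13c), ("12C", heavy_12c)):
        s = float(vec.sum())
        if abs(s - 1.0) > _SUM_TOL:
            raise ScaleError(
                f"{name} heavy abundances sum to {s}; expected relative "
                "abundances summing to 1"
            )
    delta = heavy_13c.sub(heavy_12c, fill_value=0.0)
    df = pd.DataFrame({
        "delta": delta,
        "active": delta >= delta_star,
        "threshold": delta_star,
    })
    df.index.name = "otu_id"
    return df.sort_values(["delta", "otu_id"],
                          ascending=[False, True], kind="mergesort")
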