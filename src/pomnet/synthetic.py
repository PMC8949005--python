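"""Synthetic OTU tables, PA/FL pairs and SIP gradients with planted truth.

Every downstream stage of the pipeline (diversity, incorporator calling,
lifestyle odds ratios, network inference) can be exercised against known
ground truth without any sequencing data:

* :func:`generate_modular_table` plants block-correlated communities —
  latent log-abundances follow a one-factor-per-module Gaussian design
  giving a prescribed within/between-module Pearson correlation, realized
  as multinomial reads at a fixed sequencing depth per sample.
* :func:`generate_lifestyle_pairs` emits paired particle-attached (PA) and
  free-living (FL) samples in which each OTU's expected PA:FL relative
  abundance ratio equals 10^effect exactly (an exponential tilt balances
  the two compositions so both sum to one).
* :func:`generate_sip_profiles` builds ¹³C and ¹²C density-gradient
  profiles: each OTU's abundance across fractions is a Gaussian over
  buoyant density centered at an OTU-specific base density (emulating GC
  variation); incorporators shift by ``heavy_density_shift ×
  label_atom_fraction_13C`` in the ¹³C incubation. The ¹²C control's
  1.3 atom % ¹³C is effectively natural abundance and is treated as the
  unshifted baseline.

One global seed drives everything; per-operation sub-streams are derived
deterministically so the three generators can be called in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import InvalidConfigError
from .otu_table import OtuTable
from .sip import Fraction, GradientProfile, density_to_refractive_index

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_modular_table",
    "generate_lifestyle_pairs",
    "generate_sip_profiles",
    "default_lifestyle_effects",
    "write_truth",
    "read_truth",
]

# sub-stream tags (mixed with the global seed into each RNG)
_STREAM_MODULAR = 1
_STREAM_LIFESTYLE = 2
_STREAM_SIP = 3
_STREAM_INCORP = 4

_DENSITY_BOUNDS = (1.60, 1.80)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults encode the simulated-sinking experiment: rarefaction depth
    10,475 reads/sample, 15 gradient fractions, ¹³C/¹²C substrate atom
    fractions 71.7 % / 1.3 %, and a 0.02 g/mL full-labeling density shift.
    """

    n_otus: int = 100
    n_samples_per_group: int = 30
    n_modules: int = 4
    within_module_correlation: float = 0.9
    between_module_correlation: float = 0.0
    sequencing_depth: int = 10475
    n_incorporators: int = 10
    label_atom_fraction_13C: float = 0.717
    label_atom_fraction_12C: float = 0.013
    heavy_density_shift: float = 0.02  # g/mL at full labeling
    n_fractions: int = 15
    lifestyle_effects: dict | None = None
    seed: int = 0
    # generator shape parameters (see docs/methods.md for rationale)
    latent_sigma: float = 0.6           # sd of latent log-abundance noise
    base_abundance_sigma: float = 0.6   # spread of per-OTU mean log abundance
    hubs_per_module: int = 1
    # GC-spread of unlabeled peak densities; width kept below the labeling
    # shift so labeled DNA separates, as in real full-labeling SIP
    base_density_range: tuple = (1.718, 1.726)  # g/mL
    density_bottom: float = 1.755       # densest (bottom) fraction, g/mL
    density_top: float = 1.615          # lightest (top) fraction, g/mL
    profile_sigma: float = 0.005        # Gaussian width over density, g/mL
    profile_noise_sigma: float = 0.02   # lognormal noise per fraction

    def validate(self) -> None:
        c = self
        if c.n_modules > c.n_otus:
            raise InvalidConfigError(
                f"n_modules ({c.n_modules}) > n_otus ({c.n_otus})")
        if c.n_incorporators > c.n_otus:
            raise InvalidConfigError("n_incorporators > n_otus")
        for name in ("label_atom_fraction_13C", "label_atom_fraction_12C"):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < c.within_module_correlation < 1.0:
            raise InvalidConfigError("within_module_correlation must be in (0,1)")
        if not 0.0 <= c.between_module_correlation < 1.0:
            raise InvalidConfigError("between_module_correlation must be in [0,1)")
        if c.within_module_correlation <= c.between_module_correlation:
            raise InvalidConfigError(
                "within_module_correlation must exceed between_module_correlation")
        if c.n_fractions < 3:
            raise InvalidConfigError("n_fractions must be >= 3")
        if min(c.n_otus, c.n_samples_per_group, c.sequencing_depth) < 1:
            raise InvalidConfigError("counts must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def otu_ids(self) -> list:
        width = len(str(self.n_otus))
        return [f"OTU{i + 1:0{width}d}" for i in range(self.n_otus)]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated table."""

    module_of: dict = field(default_factory=dict)
    hub_otus: set = field(default_factory=set)
    incorporators: set = field(default_factory=set)
    lifestyle_of: dict = field(default_factory=dict)


def _incorporator_set(config: SyntheticConfig) -> set:
    rng = config.rng(_STREAM_INCORP)
    ids = config.otu_ids()
    picked = rng.choice(config.n_otus, size=config.n_incorporators,
                        replace=False)
    return {ids[i] for i in sorted(picked)}


def generate_modular_table(config: SyntheticConfig) -> tuple[OtuTable, SyntheticTruth]:
    """Counts table with planted block correlation structure.

    Latent log-abundances follow a factor design: OTU i in module m has

        z_i = √b·g + √(a_i − b)·f_m + √(1 − a_i)·ε_i

    per sample (g a global factor, f_m a module factor), so any two
    same-module OTUs correlate at a = ``within_module_correlation`` and
    cross-module pairs at b = ``between_module_correlation``. Designated
    hub OTUs load more strongly on their module factor. Counts are
    multinomial draws at ``sequencing_depth`` on the per-sample softmax
    composition.
    """
    config.validate()
    rng = config.rng(_STREAM_MODULAR)
    n, s = config.n_otus, config.n_samples_per_group
    a = config.within_module_correlation
    b = config.between_module_correlation
    ids = config.otu_ids()
    module_of = {ids[i]: i % config.n_modules for i in range(n)}
    # hubs: first hubs_per_module OTUs of each module, boosted loading
    hub_otus = set()
    for m in range(config.n_modules):
        members = [o for o in ids if module_of[o] == m]
        hub_otus.update(members[:config.hubs_per_module])
    a_i = np.array([
        a + 0.6 * (1.0 - a) if ids[i] in hub_otus else a
        for i in range(n)
    ])
    mu = config.base_abundance_sigma * rng.standard_normal(n)
    g = rng.standard_normal(s)
    f = rng.standard_normal((config.n_modules, s))
    eps = rng.standard_normal((n, s))
    mods = np.array([module_of[o] for o in ids])
    # alternate the sign of the module-factor loading within each module:
    # same-module pairs still correlate at |r| = a (half positively, half
    # negatively, as in real co-occurrence modules), and the module factor
    # cancels out of the sample totals, which keeps compositional closure
    # from leaking module structure into between-module correlations
    rank_in_module = np.zeros(n, dtype=int)
    seen: dict = {}
    for i in range(n):
        m = mods[i]
        rank_in_module[i] = seen.get(m, 0)
        seen[m] = rank_in_module[i] + 1
    loading_sign = np.where(rank_in_module % 2 == 0, 1.0, -1.0)
    z = (np.sqrt(b) * g[None, :]
         + loading_sign[:, None] * np.sqrt(a_i - b)[:, None] * f[mods, :]
         + np.sqrt(1.0 - a_i)[:, None] * eps)
    log_abund = mu[:, None] + config.latent_sigma * z
    weights = np.exp(log_abund)
    probs = weights / weights.sum(axis=0, keepdims=True)
    counts = np.column_stack([
        rng.multinomial(config.sequencing_depth, probs[:, j])
        for j in range(s)
    ])
    sample_ids = [f"S{j + 1:03d}" for j in range(s)]
    meta = pd.DataFrame({
        "pressure": 0.1, "temperature": 25.0, "fraction": "PA",
        "label": "none", "replicate": sample_ids,
    }, index=pd.Index(sample_ids, name="sample_id"))
    table = OtuTable(pd.DataFrame(counts, index=ids, columns=sample_ids), meta)
    truth = SyntheticTruth(module_of=module_of, hub_otus=hub_otus,
                           incorporators=_incorporator_set(config))
    return table, truth


def default_lifestyle_effects(config: SyntheticConfig,
                              effect_size: float = 1.0,
                              fraction_affected: float = 0.4) -> dict:
    """Balanced ± effect map: equal numbers of PA- and FL-preferring OTUs.

    Pairing +effect and −effect OTUs keeps the two compositions
    normalizable with exactly matched ratios (see
    :func:`generate_lifestyle_pairs`).
    """
    ids = config.otu_ids()
    n_affected = int(round(config.n_otus * fraction_affected / 2)) * 2
    effects = {o: 0.0 for o in ids}
    for k in range(0, n_affected, 2):
        effects[ids[k]] = effect_size
        effects[ids[k + 1]] = -effect_size
    return effects


def _tilted_compositions(effects: pd.Series, masses: pd.Series):
    """Solve the exponential tilt so both fraction compositions sum to 1.

    PA weight m·10^{(1−λ)e}, FL weight m·10^{−λe} (exclusive OTUs carry
    mass on their side only); the root of Σw_PA − Σw_FL in λ makes the two
    normalizers equal, hence RA_PA/RA_FL = 10^e exactly for every finite
    effect.
    """
    e = effects.to_numpy(dtype=float)
    m = masses.to_numpy(dtype=float).copy()
    pa_excl = np.isposinf(e)
    fl_excl = np.isneginf(e)
    fin = ~(pa_excl | fl_excl)
    # exclusive masses appear on one side only and are free generator
    # choices: equalize the two exclusive totals so they cancel from the
    # balance condition
    if pa_excl.any() and fl_excl.any():
        m[fl_excl] *= m[pa_excl].sum() / m[fl_excl].sum()

    def imbalance(lam: float) -> float:
        w_pa = (m[fin] * 10.0 ** ((1.0 - lam) * e[fin])).sum() + m[pa_excl].sum()
        w_fl = (m[fin] * 10.0 ** (-lam * e[fin])).sum() + m[fl_excl].sum()
        return w_pa - w_fl

    lo, hi = -20.0, 20.0
    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if abs(f_lo) < 1e-12 and abs(f_hi) < 1e-12:
        lam = 0.5
    elif f_lo * f_hi > 0:
        raise InvalidConfigError(
            "lifestyle_effects cannot be balanced: both fractions must sum "
            "to 1, which requires mixed-sign (or zero) effects"
        )
    else:
        lam = brentq(imbalance, lo, hi, xtol=1e-14)
    w_pa = np.where(fin, m * 10.0 ** ((1.0 - lam) * np.where(fin, e, 0.0)), 0.0)
    w_pa[pa_excl] = m[pa_excl]
    w_fl = np.where(fin, m * 10.0 ** (-lam * np.where(fin, e, 0.0)), 0.0)
    w_fl[fl_excl] = m[fl_excl]
    return w_pa / w_pa.sum(), w_fl / w_fl.sum()


def generate_lifestyle_pairs(config: SyntheticConfig) -> tuple[OtuTable, SyntheticTruth]:
    """Paired PA/FL samples with exact planted odds ratios.

    ``config.lifestyle_effects`` maps OTU id → log10 odds ratio; ``+inf`` /
    ``−inf`` plant exclusive-PA / exclusive-FL OTUs (zero expected
    abundance in the other fraction). One PA and one FL multinomial sample
    at ``sequencing_depth`` is drawn per replicate.
    """
    config.validate()
    if config.lifestyle_effects is None:
        raise InvalidConfigError("lifestyle_effects must be provided")
    rng = config.rng(_STREAM_LIFESTYLE)
    ids = config.otu_ids()
    effects = pd.Series(
        {o: float(config.lifestyle_effects.get(o, 0.0)) for o in ids})
    masses = pd.Series(
        np.exp(config.base_abundance_sigma * rng.standard_normal(len(ids))),
        index=ids)
    p_pa, p_fl = _tilted_compositions(effects, masses)
    cols, metas = {}, []
    for r in range(config.n_samples_per_group):
        for frac, p in (("PA", p_pa), ("FL", p_fl)):
            sid = f"{frac}_r{r + 1:02d}"
            cols[sid] = rng.multinomial(config.sequencing_depth, p)
            metas.append({"sample_id": sid, "pressure": 0.1,
                          "temperature": 25.0, "fraction": frac,
                          "label": "none", "replicate": f"r{r + 1:02d}"})
    meta = pd.DataFrame(metas).set_index("sample_id")
    table = OtuTable(pd.DataFrame(cols, index=ids), meta)
    lifestyle_of = {}
    for o in ids:
        e = effects[o]
        if np.isposinf(e):
            lifestyle_of[o] = "exclusive-PA"
        elif np.isneginf(e):
            lifestyle_of[o] = "exclusive-FL"
        elif e > 0:
            lifestyle_of[o] = "PA"
        elif e < 0:
            lifestyle_of[o] = "FL"
    truth = SyntheticTruth(module_of={o: 0 for o in ids},
                           lifestyle_of=lifestyle_of,
                           incorporators=_incorporator_set(config))
    return table, truth


def generate_sip_profiles(config: SyntheticConfig,
                          table: OtuTable) -> list[GradientProfile]:
    """¹³C and ¹²C gradient profiles for the OTUs of ``table``.

    Per-OTU base buoyant densities are uniform on ``base_density_range``;
    the incorporator set (the same deterministic per-seed choice used by
    :func:`generate_modular_table`) shifts by ``heavy_density_shift ×
    label_atom_fraction_13C`` in the ¹³C incubation. Fraction abundances
    are density-Gaussian weights times the OTU's mean relative abundance
    in ``table``, normalized within each fraction; the fraction total
    weight is exported as a qPCR-like copy number.
    """
    config.validate()
    lo, hi = _DENSITY_BOUNDS
    if not (lo <= config.density_top < config.density_bottom <= hi):
        raise InvalidConfigError(
            f"density grid [{config.density_top}, {config.density_bottom}] "
            f"outside plausible CsCl range [{lo}, {hi}]"
        )
    rng = config.rng(_STREAM_SIP)
    ids = table.otu_ids
    mean_ra = (table.counts.div(table.counts.sum(axis=0), axis=1)
               .mean(axis=1).to_numpy())
    d_lo, d_hi = config.base_density_range
    base_density = rng.uniform(d_lo, d_hi, size=len(ids))
    incorporators = _incorporator_set(config)
    is_inc = np.array([o in incorporators for o in ids])
    densities = np.linspace(config.density_bottom, config.density_top,
                            config.n_fractions)
    shift_13c = config.heavy_density_shift * config.label_atom_fraction_13C
    profiles = []
    for label in ("13C", "12C"):
        centers = base_density + (shift_13c * is_inc if label == "13C" else 0.0)
        noise = np.exp(config.profile_noise_sigma
                       * rng.standard_normal((len(ids), config.n_fractions)))
        fractions = []
        for fi, rho in enumerate(densities):
            w = (mean_ra
                 * np.exp(-((rho - centers) ** 2)
                          / (2.0 * config.profile_sigma ** 2))
                 * noise[:, fi])
            total = w.sum()
            abund = pd.Series(w / total, index=ids)
            fractions.append(Fraction(
                fraction_index=fi + 1,
                refractive_index=density_to_refractive_index(rho),
                buoyant_density=float(rho),
                abundances=abund,
                copy_number=float(total * 1e8),  # arbitrary copies/µL scale
            ))
        profiles.append(GradientProfile(f"sim-{label}", label, fractions))
    return profiles


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Persist planted truth as a tab-delimited table (one row per OTU)."""
    otus = sorted(set(truth.module_of) | truth.hub_otus | truth.incorporators
                  | set(truth.lifestyle_of), key=str)
    df = pd.DataFrame({
        "module": [truth.module_of.get(o, -1) for o in otus],
        "hub": [int(o in truth.hub_otus) for o in otus],
        "incorporator": [int(o in truth.incorporators) for o in otus],
        "lifestyle": [truth.lifestyle_of.get(o, "none") for o in otus],
    }, index=pd.Index(otus, name="otu_id"))
    df.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SyntheticTruth(
        module_of={o: int(m) for o, m in df["module"].items() if m >= 0},
        hub_otus={o for o, h in df["hub"].items() if h},
        incorporators={o for o, i in df["incorporator"].items() if i},
        lifestyle_of={o: l for o, l in df["lifestyle"].items() if l != "none"},
    )
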