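"""Per-sample alpha-diversity indices.

Implements the index set reported for the particle-sinking incubations:
observed richness, Shannon entropy, Simpson evenness, Chao1 and ACE richness
estimators, and Good's coverage. Indices are intended to be computed on
rarefied counts (resample first, then estimate) so that samples are
comparable at a common depth.

Notes on estimator variants
---------------------------
* Shannon is returned in nats by default (``base`` flag for log2); the
  logarithm base is recorded in the output table so results are
  self-describing.
* Simpson evenness is E = (1/D)/S_obs with D = Σ p_i² (inverse Simpson over
  observed richness). A finite-sample variant using
  Σ n_i(n_i−1)/(N(N−1)) is available via ``finite_sample=True``.
* Chao1 uses the classic form S_obs + n1²/(2·n2); when there are no
  doubletons (or on request) the bias-corrected form
  S_obs + n1(n1−1)/(2(n2+1)) is used.
* ACE uses the standard abundance-based coverage estimator with rare
  cutoff 10; if every rare read is a singleton (C_ace = 0) it falls back to
  Chao1 with a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DegenerateSampleError
from .otu_table import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "observed_otus",
    "shannon",
    "simpson_evenness",
    "chao1",
    "ace",
    "goods_coverage",
    "alpha_diversity_table",
]


def _positive(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise DegenerateSampleError("all-zero count vector")
    return arr


def observed_otus(counts) -> int:
    """Number of OTUs with at least one read."""
    return int(_positive(counts).size)


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = −Σ p_i log p_i over nonzero p_i = n_i/N.

    Natural log (nats) unless ``base`` is given.
    """
    arr = _positive(counts)
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson_evenness(counts, finite_sample: bool = False) -> float:
    """Simpson evenness E = (1/D)/S_obs.

    D = Σ p_i² by default; with ``finite_sample`` D is the unbiased
    Σ n_i(n_i−1)/(N(N−1)).
    """
    arr = _positive(counts)
    n = arr.sum()
    if finite_sample:
        if n < 2:
            raise DegenerateSampleError("finite-sample Simpson needs N >= 2")
        d = float((arr * (arr - 1)).sum() / (n * (n - 1)))
        if d == 0.0:
            # all singletons: dominance indistinguishable from 0; evenness 1
            return 1.0
    else:
        p = arr / n
        d = float((p ** 2).sum())
    return (1.0 / d) / arr.size


def chao1(counts, bias_corrected: bool = False) -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    arr = _positive(counts)
    s_obs = arr.size
    n1 = int((arr == 1).sum())
    n2 = int((arr == 2).sum())
    if bias_corrected or n2 == 0:
        return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    return s_obs + n1 ** 2 / (2.0 * n2)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (ACE).

    OTUs with counts ≤ ``rare_cutoff`` form the rare class. With
    N_rare reads in the rare class, sample coverage C = 1 − n1/N_rare and

        ACE = S_abund + S_rare/C + (n1/C)·γ²,

    where γ² is the rare-class coefficient of variation
    max(0, S_rare/C · Σ i(i−1)F_i / (N_rare(N_rare−1)) − 1).
    """
    arr = _positive(counts)
    rare = arr[arr <= rare_cutoff]
    s_abund = int((arr > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    n1 = int((rare == 1).sum())
    c_ace = 1.0 - n1 / n_rare
    if c_ace == 0.0:
        logger.warning("ace: all rare reads are singletons; falling back to chao1")
        return chao1(counts)
    top = sum(i * (i - 1) * int((rare == i).sum())
              for i in range(1, rare_cutoff + 1))
    if n_rare > 1:
        gamma = max((s_rare / c_ace) * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    else:
        gamma = 0.0
    return s_abund + s_rare / c_ace + (n1 / c_ace) * gamma


def goods_coverage(counts) -> float:
    """Good's coverage 1 − n1/N (fraction of reads from seen-again OTUs)."""
    arr = _positive(counts)
    n = arr.sum()
    n1 = int((arr == 1).sum())
    return 1.0 - n1 / n


def alpha_diversity_table(table: OtuTable, shannon_base: float | None = None,
                          finite_sample_simpson: bool = False) -> pd.DataFrame:
    """All indices for every sample of an :class:`OtuTable`.

    Returns a DataFrame indexed by sample id with columns
    ``observed_otus, shannon, shannon_log_base, simpson_evenness, chao1,
    ace, goods_coverage``.
    """
    records = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        records[sid] = {
            "observed_otus": observed_otus(col),
            "shannon": shannon(col, base=shannon_base),
            "shannon_log_base": shannon_base if shannon_base else np.e,
            "simpson_evenness": simpson_evenness(
                col, finite_sample=finite_sample_simpson),
            "chao1": chao1(col),
            "ace": ace(col),
            "goods_coverage": goods_coverage(col),
        }
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "sample_id"
    return df
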