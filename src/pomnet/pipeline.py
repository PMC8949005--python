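"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` chains the stages — simulate → rarefy/filter → diversity →
SIP incorporator calling → lifestyle classification → network inference —
writing every intermediate artifact plus a manifest (parameters, seeds,
SHA-256 checksums) sufficient to reproduce the run bit-for-bit. ``report``
consolidates a completed run directory into a markdown summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import alpha_diversity_table
from .exceptions import InvalidConfigError
from .lifestyle import classify_lifestyles
from .network import (build_network, detect_modules, pearson_matrix,
                      random_null, role_summary, topology_stats, zi_pi)
from .otu_table import (OtuTable, filter_prevalence, rarefy, read_otu_table,
                        to_relative, write_otu_table)
from .rmt import default_grid, rmt_threshold
from .sip import (identify_active_otus, pool_fractions,
                  select_heavy_fractions, write_gradient_profiles)
from .synthetic import (SyntheticConfig, default_lifestyle_effects,
                        generate_lifestyle_pairs, generate_modular_table,
                        generate_sip_profiles, write_truth)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report", "REPORT_TABLES"]

#: the six consolidated report tables every complete run emits
REPORT_TABLES = [
    "diversity.tsv",
    "active_calls.tsv",
    "lifestyle_records.tsv",
    "lifestyle_summary.tsv",
    "network_stats.tsv",
    "zp_data.tsv",
]


@dataclass
class PipelineConfig:
    """All stage parameters with their study-anchored defaults."""

    out_dir: str = "pomnet_run"
    table_path: str | None = None       # None → simulate
    meta_path: str | None = None
    taxonomy_path: str | None = None
    rarefaction_depth: int = 10475
    prevalence_min_samples: int = 7
    heavy_window: tuple | None = (1.730, 1.746)  # g/mL
    delta_star: float = 0.01
    lifestyle_floor: float = 0.01
    network_grid: tuple = (0.30, 0.99, 0.01)
    network_alpha: float = 0.05
    n_nulls: int = 100
    seed: int = 0
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        if self.heavy_window is None or len(self.heavy_window) != 2 \
                or not self.heavy_window[0] < self.heavy_window[1]:
            raise InvalidConfigError(
                "heavy_window must be (lo, hi) with lo < hi; the heavy "
                "density window is a required, logged analysis choice"
            )
        if self.rarefaction_depth < 1:
            raise InvalidConfigError("rarefaction_depth must be positive")
        if not 0 <= self.delta_star <= 1:
            raise InvalidConfigError("delta_star must be a proportion")
        start, stop, step = self.network_grid
        if not (0 < start < stop < 1 and step > 0):
            raise InvalidConfigError("network_grid must be (start, stop, step) in (0,1)")
        self.simulate.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["simulate"] = dataclasses.asdict(self.simulate)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulate", {}) or {}
        for key in ("heavy_window", "network_grid", "base_density_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("base_density_range",):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        return cls(simulate=SyntheticConfig(**sim), **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run manifest.

    In simulate mode (no ``table_path``) the synthetic generators provide
    the community table, PA/FL pairs and SIP gradients, and the planted
    truth is written alongside the artifacts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params_path = out / "config.yaml"
    config.to_yaml(params_path)
    stage = "simulate"
    try:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        if config.table_path is None:
            table, truth = generate_modular_table(sim)
            write_otu_table(table, out / "otu_table.tsv",
                            out / "sample_meta.tsv")
            write_truth(truth, out / "truth.tsv")
            if sim.lifestyle_effects is None:
                sim = dataclasses.replace(
                    sim, lifestyle_effects=default_lifestyle_effects(sim))
            ls_table, ls_truth = generate_lifestyle_pairs(sim)
            write_otu_table(ls_table, out / "lifestyle_table.tsv",
                            out / "lifestyle_meta.tsv")
            write_truth(ls_truth, out / "lifestyle_truth.tsv")
            profiles = generate_sip_profiles(sim, table)
            write_gradient_profiles(profiles, out / "gradient_profiles.tsv")
        else:
            table = read_otu_table(config.table_path, config.meta_path,
                                   config.taxonomy_path)
            ls_table, profiles = table, None

        stage = "rarefy"
        depth = min(config.rarefaction_depth,
                    int(table.sample_sums().min()))
        rare = rarefy(table, depth, seed=config.seed)
        write_otu_table(rare, out / "rarefied_table.tsv")

        stage = "diversity"
        div = alpha_diversity_table(rare)
        div.to_csv(out / "diversity.tsv", sep="\t")

        stage = "sip-call"
        if profiles is not None:
            by_label = {p.label: p for p in profiles}
            pooled = {
                lab: pool_fractions(
                    select_heavy_fractions(by_label[lab], config.heavy_window))
                for lab in ("13C", "12C")
            }
            calls = identify_active_otus(pooled["13C"], pooled["12C"],
                                         config.delta_star)
            calls.to_csv(out / "active_calls.tsv", sep="\t")
        else:
            pd.DataFrame(columns=["delta", "active", "threshold"]).to_csv(
                out / "active_calls.tsv", sep="\t", index_label="otu_id")

        stage = "lifestyle"
        ls_rel = to_relative(ls_table)
        ls = classify_lifestyles(ls_rel, ls_table.sample_meta,
                                 config.lifestyle_floor)
        ls.records.to_csv(out / "lifestyle_records.tsv", sep="\t", index=False)
        ls.summary.to_csv(out / "lifestyle_summary.tsv", sep="\t")

        stage = "network"
        filtered = filter_prevalence(rare, config.prevalence_min_samples)
        rel = to_relative(filtered)
        matrix = pearson_matrix(rel)
        start, stop, step = config.network_grid
        scan = rmt_threshold(matrix, default_grid(start, stop, step),
                             config.network_alpha)
        net = build_network(matrix, scan.selected, filtered.taxonomy)
        partition = detect_modules(net)
        stats = topology_stats(net, partition)
        roles = zi_pi(net, partition)
        null = random_null(net, config.n_nulls, seed=config.seed)
        scan.scan.to_csv(out / "rmt_scan.tsv", sep="\t", index=False)
        net.edge_list().to_csv(out / "edge_list.tsv", sep="\t", index=False)
        roles.to_csv(out / "zp_data.tsv", sep="\t")
        stats_df = pd.DataFrame({"simulated": stats.as_series()})
        for key in ("avg_cc", "gd", "modularity"):
            stats_df.loc[f"null_{key}_mean", "simulated"] = null.null_mean[key]
            stats_df.loc[f"null_{key}_sd", "simulated"] = null.null_sd[key]
            stats_df.loc[f"null_{key}_p", "simulated"] = null.p_values[key]
        stats_df.to_csv(out / "network_stats.tsv", sep="\t",
                        index_label="feature")
    except Exception as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    artifacts = sorted(p.name for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "pomnet_version": __version__,
        "seed": config.seed,
        "parameters": yaml.safe_load(params_path.read_text()),
        "checksums": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    logger.info("run complete: %d artifacts in %s", len(artifacts), out)
    return manifest


def report(run_dir: str | Path) -> str:
    """Consolidate a completed run into ``report.md``; returns its text.

    Raises :class:`FileNotFoundError` listing any missing artifact.
    """
    run = Path(run_dir)
    missing = [t for t in REPORT_TABLES if not (run / t).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run {run}: missing artifacts {missing}")
    lines = [f"# pomnet run report — {run.name}", ""]
    for name in REPORT_TABLES:
        df = pd.read_csv(run / name, sep="\t")
        lines.append(f"## {name}")
        lines.append(f"rows: {len(df)}")
        lines.append("")
        lines.append(df.head(20).to_markdown(index=False))
        lines.append("")
    text = "\n".join(lines)
    (run / "report.md").write_text(text)
    return text
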