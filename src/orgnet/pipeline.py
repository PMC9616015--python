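"""End-to-end orchestration: per-network ingest → filter → collapse →
reconstruction → symmetrization → metrics → sector aggregation, and the
side-by-side comparison of several networks.

Configuration is a YAML/JSON document::

    seed: 1
    output_dir: out
    layers: [contact, referral]
    top_k: 10
    networks:
      - name: net_a                     # file-based network
        roster: roster.csv
        reports: reports.csv
        responses: responses.csv
        threshold:                      # optional boundary filter
          attribute: clients_2017
          minimum: 6
          sectors: [specialized_youth_care]
      - name: net_b                     # synthetic network
        synthetic: {n_orgs: 86, response_rate: 0.57}

Every stage is logged with row/tie counts and the share of survey-invisible
dyads; a validation failure in one network aborts that network with a
diagnostic while the others are still processed.  All randomness flows from
the single config seed (network ``i`` uses ``seed + i``); the run manifest
records it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import build, metrics, sectors, synthetic
from .errors import ConfigurationError, OrgnetError
from .ingest import (
    LAYERS,
    Roster,
    TieReportSet,
    apply_threshold_filter,
    collapse_respondents,
)
from .metrics import MetricsPanel

log = logging.getLogger("orgnet")

#: Row order of the cross-network comparison table.
PANEL_ROWS = (
    "n_sectors",
    "n_orgs",
    "active",
    "isolates",
    "ties_ordered",
    "density",
    "avg_degree",
    "centralization",
)


@dataclass(frozen=True)
class ThresholdSpec:
    attribute: str
    minimum: float
    sectors: tuple[str, ...]


@dataclass(frozen=True)
class NetworkSpec:
    """One network: either file inputs or a synthetic configuration."""

    name: str
    roster: str | None = None
    reports: str | None = None
    responses: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    threshold: ThresholdSpec | None = None

    def __post_init__(self) -> None:
        file_based = self.roster is not None
        if file_based == (self.synthetic is not None):
            raise ConfigurationError(
                f"network {self.name!r} must have either file inputs or a synthetic block"
            )
        if file_based and self.reports is None:
            raise ConfigurationError(f"network {self.name!r} has a roster but no reports file")


@dataclass(frozen=True)
class PipelineConfig:
    networks: tuple[NetworkSpec, ...]
    layers: tuple[str, ...] = LAYERS
    output_dir: str | None = None
    seed: int = 0
    top_k: int = 10

    def __post_init__(self) -> None:
        if not self.networks:
            raise ConfigurationError("config must name at least one network")
        bad = set(self.layers) - set(LAYERS)
        if bad:
            raise ConfigurationError(f"unknown layers {sorted(bad)}; allowed: {LAYERS}")

    @classmethod
    def from_dict(cls, doc: dict, base_dir: Path | None = None) -> "PipelineConfig":
        def _path(p):
            if p is None:
                return None
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise ConfigurationError(f"input path does not exist: {p}")
            return str(p)

        nets = []
        for i, nd in enumerate(doc.get("networks", [])):
            synth = None
            if "synthetic" in nd:
                synth_args = dict(nd["synthetic"])
                synth_args.setdefault("seed", int(doc.get("seed", 0)) + i)
                if "multi_respondent_sectors" in synth_args:
                    synth_args["multi_respondent_sectors"] = frozenset(
                        synth_args["multi_respondent_sectors"]
                    )
                synth = synthetic.SyntheticConfig(**synth_args)
            thr = None
            if "threshold" in nd:
                td = nd["threshold"]
                thr = ThresholdSpec(
                    attribute=td["attribute"],
                    minimum=float(td["minimum"]),
                    sectors=tuple(td.get("sectors", ())),
                )
            nets.append(
                NetworkSpec(
                    name=str(nd.get("name", f"network_{i + 1}")),
                    roster=_path(nd.get("roster")),
                    reports=_path(nd.get("reports")),
                    responses=_path(nd.get("responses")),
                    synthetic=synth,
                    threshold=thr,
                )
            )
        return cls(
            networks=tuple(nets),
            layers=tuple(doc.get("layers", LAYERS)),
            output_dir=doc.get("output_dir"),
            seed=int(doc.get("seed", 0)),
            top_k=int(doc.get("top_k", 10)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc or {}, base_dir=path.parent)


@dataclass
class NetworkResult:
    """Everything computed for one network."""

    name: str
    roster: Roster
    invited: int
    responding: int
    panels: dict[str, MetricsPanel] = field(default_factory=dict)
    adjacencies: dict[str, build.Adjacency] = field(default_factory=dict)
    rankings: dict[str, pd.DataFrame] = field(default_factory=dict)
    sector_graphs: dict[str, sectors.SectorGraph] = field(default_factory=dict)

    @property
    def response_pct(self) -> int:
        return metrics._round_half_up(100.0 * self.responding / self.invited)


@dataclass
class ComparisonReport:
    """Per-network results plus cross-network metric tables."""

    results: dict[str, NetworkResult]
    failures: dict[str, str]
    seed: int

    def comparison_table(self, layer: str) -> pd.DataFrame:
        """Cross-network table: one column per network, the standard panel
        rows; rounding applied here, at rendering time only."""
        cols = {}
        for name, res in self.results.items():
            panel = res.panels.get(layer)
            if panel is None:
                continue
            r = panel.rounded()
            cols[name] = {
                "n_sectors": r["n_sectors"],
                "n_orgs": r["n_orgs"],
                "active": f"{r['active_orgs']} ({r['active_pct']}%)",
                "isolates": r["isolates"],
                "ties_ordered": r["ties_ordered"],
                "density": f"{r['density']:.3f}",
                "avg_degree": f"{r['avg_degree']:.2f}",
                "centralization": f"{r['centralization']:.3f}",
            }
        return pd.DataFrame(cols).reindex(list(PANEL_ROWS))

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "networks": {
                name: {
                    "invited": res.invited,
                    "responding": res.responding,
                    "response_pct": res.response_pct,
                    "layers": {
                        layer: {
                            **res.panels[layer].rounded(),
                            "reconstructed_dyad_share": round(
                                res.adjacencies[layer].reconstructed_share(), 4
                            ),
                        }
                        for layer in res.panels
                    },
                }
                for name, res in self.results.items()
            },
            "failures": self.failures,
        }


def summarize_differentiation(roster: Roster) -> pd.DataFrame:
    """Composition summary: organizations per sector, task mix, sector count.

    One row per sector plus a TOTAL row; the ``n_sectors`` on the TOTAL row
    is the number of sectors present.
    """
    if len(roster) == 0:
        raise OrgnetError("roster is empty")
    rows = []
    for sector in roster.sectors():
        members = [o for o in roster if o.sector == sector]
        row = {"sector": sector, "n_orgs": len(members)}
        for task in sorted({"gatekeeper", "signaling", "providing_services"}):
            row[task] = sum(task in o.tasks for o in members)
        rows.append(row)
    total = {
        "sector": "TOTAL",
        "n_orgs": len(roster),
        **{
            task: sum(r[task] for r in rows)
            for task in sorted({"gatekeeper", "signaling", "providing_services"})
        },
    }
    frame = pd.DataFrame(rows + [total])
    frame["n_sectors"] = len(roster.sectors())
    return frame


def _load_network(spec: NetworkSpec, seed: int) -> tuple[Roster, TieReportSet]:
    if spec.synthetic is not None:
        roster, _truth, reports = synthetic.generate_survey(spec.synthetic)
        return roster, reports
    roster = Roster.from_csv(spec.roster)
    reports = TieReportSet.from_csv(spec.reports, spec.responses)
    return roster, reports


def analyze_network(
    spec: NetworkSpec,
    layers: tuple[str, ...] = LAYERS,
    top_k: int = 10,
    seed: int = 0,
) -> NetworkResult:
    """Run the full single-network pipeline and return its results."""
    roster, reports = _load_network(spec, seed)
    log.info("[%s] roster: %d organizations, %d sectors, %d respondents",
             spec.name, len(roster), len(roster.sectors()), len(roster.respondent_ids))
    if spec.threshold is not None:
        before = len(roster)
        roster = apply_threshold_filter(
            roster, spec.threshold.attribute, spec.threshold.minimum, spec.threshold.sectors
        )
        reports = reports.restrict(roster)
        log.info("[%s] threshold filter %s>=%s on %s: %d -> %d organizations",
                 spec.name, spec.threshold.attribute, spec.threshold.minimum,
                 list(spec.threshold.sectors), before, len(roster))

    # organization responds iff >= 1 of its boundary spanners responded
    responding = sum(
        any(reports.responded.get(r, False) for r in org.respondent_ids) for org in roster
    )
    result = NetworkResult(
        name=spec.name, roster=roster, invited=len(roster), responding=responding
    )
    log.info("[%s] response: %d of %d organizations (%d%%)",
             spec.name, responding, len(roster), result.response_pct)

    for layer in layers:
        report = collapse_respondents(roster, reports, layer)
        adj = build.build_adjacency(report)
        panel = metrics.compute_panel(adj, roster)
        result.adjacencies[layer] = adj
        result.panels[layer] = panel
        result.rankings[layer] = metrics.top_k_central(adj, roster, min(top_k, adj.n))
        if len(roster.sectors()) >= 2:
            result.sector_graphs[layer] = sectors.aggregate_to_sectors(adj, roster)
        log.info(
            "[%s/%s] ties=%d density=%.3f avg_degree=%.2f centralization=%.3f "
            "isolates=%d unrecoverable_dyads=%.1f%%",
            spec.name, layer, panel.ties_ordered, panel.density, panel.avg_degree,
            panel.centralization, panel.isolates, 100 * adj.reconstructed_share(),
        )
    return result


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Run every configured network; a failure in one aborts only that one."""
    results: dict[str, NetworkResult] = {}
    failures: dict[str, str] = {}
    for i, spec in enumerate(config.networks):
        try:
            results[spec.name] = analyze_network(
                spec, layers=config.layers, top_k=config.top_k, seed=config.seed + i
            )
        except OrgnetError as exc:
            log.error("[%s] aborted: %s", spec.name, exc)
            failures[spec.name] = str(exc)
    report = ComparisonReport(results=results, failures=failures, seed=config.seed)
    if config.output_dir is not None:
        write_report(report, config.output_dir, layers=config.layers)
    return report


def write_report(
    report: ComparisonReport, output_dir, layers: tuple[str, ...] = LAYERS
) -> None:
    """Render a ComparisonReport to CSV/JSON/GraphML/DOT files under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in report.results.items():
        ndir = out / name
        ndir.mkdir(exist_ok=True)
        res.roster.to_csv(ndir / "roster.csv")
        summarize_differentiation(res.roster).to_csv(
            ndir / "differentiation.csv", index=False
        )
        for layer, adj in res.adjacencies.items():
            build.write_adjacency_csv(adj, ndir / f"adjacency_{layer}.csv")
            build.write_edge_list_csv(adj, ndir / f"edges_{layer}.csv")
            build.write_graphml(adj, ndir / f"network_{layer}.graphml", res.roster)
            res.rankings[layer].to_csv(ndir / f"top_central_{layer}.csv", index=False)
            with open(ndir / f"panel_{layer}.json", "w", encoding="utf-8") as fh:
                json.dump(res.panels[layer].rounded(), fh, indent=2)
            if layer in res.sector_graphs:
                sg = res.sector_graphs[layer]
                sg.to_csv(ndir / f"sectors_{layer}.csv")
                sg.to_dot(ndir / f"sectors_{layer}.dot")
    for layer in layers:
        table = None
        if report.results:
            table = report.comparison_table(layer)
        if table is not None and not table.empty:
            table.to_csv(out / f"comparison_{layer}.csv", index_label="metric")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report.manifest(), fh, indent=2)
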