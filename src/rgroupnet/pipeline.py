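"""End-to-end pipeline: filter -> decompose -> series -> network -> hierarchies.

:class:`RunConfig` collects every tunable threshold with the defaults used
throughout: molecular weight cap 1000 Da, R-group cap 13 heavy atoms,
minimum series size 3, up to 4 substitution sites per core, unique series
membership, removal of hydrogen/methyl/phenyl for the final network, and
5 x 2 hierarchies for the top 500 R-groups.  :func:`run_pipeline` executes
the chain, writes all exports and returns a manifest of Fig.-style counters
(compounds in/out, series, sites, unique R-groups, global and final network
sizes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import compound_io, hierarchy, network, series as series_mod
from .compound_io import CompoundRecord
from .fragmentation import FragmentationConfig, enumerate_decompositions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mw_max: float = 1000.0
    rgroup_max_heavy: int = 13
    min_members: int = 3
    max_sites: int = 4
    assignment_mode: str = "unique"
    remove_set: tuple[str, ...] = tuple(sorted(network.DEFAULT_REMOVE))
    drop_isolated: bool = True
    top_k: int = 500
    n_first: int = 5
    n_second: int = 2
    seed: int = 0
    hydrogen_cuts: bool = True
    cut_budget: int = 500_000
    min_edge_weight: int | None = None

    def __post_init__(self) -> None:
        for name in ("mw_max", "rgroup_max_heavy", "min_members", "max_sites",
                     "top_k", "n_first", "n_second", "cut_budget"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def fragmentation(self) -> FragmentationConfig:
        return FragmentationConfig(
            max_sites=self.max_sites,
            rgroup_max_heavy=self.rgroup_max_heavy,
            hydrogen_cuts=self.hydrogen_cuts,
            cut_budget=self.cut_budget,
        )


@dataclass
class PipelineResult:
    records: list[CompoundRecord]
    series: list
    sites: list
    global_net: object
    final_net: object
    database: list
    manifest: dict


def _checksum(records: Sequence[CompoundRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(f"{r.compound_id}\t{r.smiles}\n".encode())
    return h.hexdigest()


def run_pipeline(
    records: Sequence[CompoundRecord],
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on canonicalized records.

    When ``outdir`` is given, writes compounds.csv, series.csv,
    site_table.csv, edges_global.csv, edges.csv (final network),
    database.xml and manifest.json there.
    """
    cfg = config or RunConfig()
    frag_cfg = cfg.fragmentation()
    kept = compound_io.filter_compounds(records, cfg.mw_max)
    log.info("filter: kept %d of %d compounds", len(kept), len(records))
    decompositions = []
    for rec in kept:
        decompositions.extend(enumerate_decompositions(rec, frag_cfg))
    log.info("fragmentation: %d decompositions", len(decompositions))
    groups = series_mod.group_by_core(decompositions, records=kept)
    all_series = series_mod.build_series(
        groups, min_members=cfg.min_members, assignment_mode=cfg.assignment_mode
    )
    sites = series_mod.build_site_tables(all_series)
    global_net = network.build_network(sites)
    final_net = network.refine_network(
        global_net, remove=cfg.remove_set, drop_isolated=cfg.drop_isolated
    )
    db_source = final_net if final_net.number_of_nodes() else final_net
    database = (
        hierarchy.build_database(db_source, cfg.top_k, cfg.n_first, cfg.n_second)
        if final_net.number_of_nodes()
        else []
    )
    manifest = {
        "config": dataclasses.asdict(cfg),
        "input_checksum": _checksum(records),
        "counters": {
            "compounds_in": len(records),
            "compounds_kept": len(kept),
            "decompositions": len(decompositions),
            "series": len(all_series),
            "substitution_sites": len(sites),
            "unique_rgroups": len(network.unique_rgroups(sites)),
            "global_nodes": global_net.number_of_nodes(),
            "global_edges": global_net.number_of_edges(),
            "final_nodes": final_net.number_of_nodes(),
            "final_edges": final_net.number_of_edges(),
            "hierarchies": len(database),
        },
    }
    result = PipelineResult(list(kept), all_series, sites, global_net, final_net,
                            database, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        compound_io.write_compound_table(kept, outdir / "compounds.csv")
        series_mod.write_series_table(all_series, outdir / "series.csv")
        series_mod.write_site_tables(sites, outdir / "site_table.csv")
        network.write_edge_list(global_net, outdir / "edges_global.csv",
                                min_weight=cfg.min_edge_weight)
        network.write_edge_list(final_net, outdir / "edges.csv",
                                min_weight=cfg.min_edge_weight)
        if database:
            hierarchy.write_xml(database, outdir / "database.xml")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
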