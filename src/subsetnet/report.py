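"""Report bundle: summary JSON, TSV tables, GraphML networks and a run log.

JSON outputs are deterministic for a given seeded run (sorted keys, no
timestamps); the plain-text run log carries config, seeds and versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import networkx
import numpy
import pandas
import scipy

import subsetnet
from subsetnet import network
from subsetnet.pipeline import PipelineResult


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(result: PipelineResult, outdir, config_echo: dict | None = None) -> Path:
    """Write the full report bundle under ``outdir``; returns the path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    for s, de in result.de.items():
        de.to_tsv(out / f"de_{s}.tsv")
    result.cpm.to_csv(out / "cpm.tsv", sep="\t", index_label="gene_id")
    if len(result.ora):
        from subsetnet.enrichment import write_ora_tsv
        write_ora_tsv(result.ora, out / "ora.tsv")

    venn = {
        "de_transcripts": result.de_venn.as_dict(),
        "modulators": result.modulators.as_dict(),
    }
    _write_json(venn, out / "venn.json")

    modules = {
        s: [m.as_dict() for m in mods]
        for s, mods in result.subnet_modules.items()
    }
    _write_json(modules, out / "modules.json")
    for s, table in result.hub_tables.items():
        table.to_csv(out / f"hubs_{s}.tsv", sep="\t", index_label="node")

    network.write_graphml(result.expanded_net, out / "expanded_network.graphml")
    for s, nodes in result.subnet_nodes.items():
        if nodes:
            network.write_graphml(result.clean_net.subgraph(nodes).copy(),
                                  out / f"subnetwork_{s}.graphml")

    summary = {
        "n_genes_tested": int(len(result.de["A"].table)),
        "de_counts": {s: len(r.de_genes()) for s, r in result.de.items()},
        "de_venn": result.de_venn.as_dict(),
        "modulator_venn": result.modulators.venn.as_dict(),
        "subnetwork_sizes": {s: len(n) for s, n in result.subnet_nodes.items()},
        "concordance": result.concordance.as_dict(),
        "ora_retained_terms": int(len(result.ora)),
        "size_factors": {k: float(v) for k, v in result.factors.items()},
        "config": config_echo or {},
    }
    _write_json(summary, out / "summary.json")

    with open(out / "run.log", "w") as fh:
        fh.write(f"subsetnet {subsetnet.__version__}\n")
        fh.write(f"python {platform.python_version()}\n")
        for mod in (numpy, scipy, pandas, networkx):
            fh.write(f"{mod.__name__} {mod.__version__}\n")
        fh.write(f"config: {json.dumps(config_echo or {}, sort_keys=True)}\n")
    return out


def require_stages(result: PipelineResult) -> None:
    """Raise a clear error naming any absent upstream stage."""
    stages = {
        "differential expression": result.de,
        "normalisation": result.factors is not None,
        "network cleaning": result.clean_net is not None,
        "modulator partition": result.modulators is not None,
    }
    missing = [name for name, ok in stages.items() if not ok]
    if missing:
        raise ValueError(f"missing upstream stage output: {missing[0]}")
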