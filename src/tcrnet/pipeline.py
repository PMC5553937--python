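"""Figure-level orchestration: end-to-end analyses producing tidy tables.

Each runner consumes cohorts (from disk or the simulator), applies the
network / sharing / stats machinery, and returns plain DataFrames; the
CLI writes them as CSV alongside optional graph exports.  Runs are
deterministic given the seed registry.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as netmod
from . import sharing as shmod
from .repertoires import Cohort, top_n, random_subsets
from .stats import repertoire_gini, standard_error


def _net_summary(net) -> tuple[int, int]:
    return netmod.clustered_node_count(net), netmod.edge_count(net)


def run_figure1(cohort: Cohort, reference: Cohort, n: int = 1000,
                n_random_reps: int = 10, seed: int = 0, outdir=None) -> dict:
    """Per-individual top-N vs random-N networks: clustered-node and edge
    counts, mean degree and betweenness by sharing level (SE across
    individuals)."""
    ref_table = shmod.sharing_levels(reference)
    rows, degree_rows, btw_rows = [], [], []
    for rep in cohort:
        size = min(n, len(rep))
        sub = top_n(rep, size)
        net = netmod.network_from_repertoire(sub, sharing=ref_table,
                                             provenance=f"top:{size}")
        cn, ec = _net_summary(net)
        rows.append({"individual": rep.individual_id, "condition": "top",
                     "clustered_nodes": cn, "edges": ec,
                     "accumulated_frequency": sub.accumulated_frequency()})
        for s, md in shmod.mean_degree_by_sharing(net, ref_table).items():
            degree_rows.append({"individual": rep.individual_id, "condition": "top",
                                "sharing": s, "mean_degree": md})
        for s, mb in shmod.mean_betweenness_by_sharing(net, ref_table).items():
            btw_rows.append({"individual": rep.individual_id, "condition": "top",
                             "sharing": s, "mean_betweenness": mb})
        cns, ecs, afs = [], [], []
        for rnd in random_subsets(rep, size, n_random_reps, seed):
            rnet = netmod.build_network(rnd.sequences)
            cn, ec = _net_summary(rnet)
            cns.append(cn); ecs.append(ec); afs.append(rnd.accumulated_frequency())
        rows.append({"individual": rep.individual_id, "condition": "random",
                     "clustered_nodes": float(np.mean(cns)), "edges": float(np.mean(ecs)),
                     "accumulated_frequency": float(np.mean(afs))})
    networks = pd.DataFrame(rows)
    summary = networks.groupby("condition").agg(
        mean_clustered_nodes=("clustered_nodes", "mean"),
        sd_clustered_nodes=("clustered_nodes", "std"),
        se_clustered_nodes=("clustered_nodes", standard_error),
        mean_edges=("edges", "mean"),
        sd_edges=("edges", "std"),
        mean_accumulated_frequency=("accumulated_frequency", "mean"),
    ).reset_index()
    out = {"networks": networks, "summary": summary,
           "degree_by_sharing": pd.DataFrame(degree_rows),
           "betweenness_by_sharing": pd.DataFrame(btw_rows)}
    if outdir:
        _write_tables(out, outdir, "fig1")
    return out


def run_figure2(mouse: Cohort, human: Cohort,
                scheme: shmod.CategoryScheme | None = None,
                n: int = 1000, outdir=None) -> dict:
    """Cross-species sharing curves, the CS-public set, and the mean degree
    of the four sharing categories within per-individual top-N networks."""
    scheme = scheme or shmod.CategoryScheme.scaled(len(mouse), len(human))
    mouse_table = shmod.sharing_levels(mouse)
    human_table = shmod.sharing_levels(human)
    cs = shmod.cs_public(mouse_table, human_table, scheme)

    curves = []
    for name, a, b in (("mouse", mouse, human), ("human", human, mouse)):
        res = shmod.cross_species_sharing(a, b)
        for level in sorted(res.fraction_by_level):
            shared, total = res.counts_by_level[level]
            curves.append({"species": name, "sharing_level": level,
                           "fraction_in_other": res.fraction_by_level[level],
                           "n_shared": shared, "n_total": total})

    def category(aa: str) -> str:
        return scheme.category(mouse_table.level(aa), human_table.level(aa))

    cat_rows = []
    for cohort_name, cohort in (("mouse", mouse), ("human", human)):
        for rep in cohort:
            sub = top_n(rep, min(n, len(rep)))
            net = netmod.build_network(sub.sequences)
            by_cat: dict[str, list[int]] = {}
            for node in net.nodes:
                by_cat.setdefault(category(node), []).append(net.degree(node))
            for cat, degs in by_cat.items():
                cat_rows.append({"cohort": cohort_name, "individual": rep.individual_id,
                                 "category": cat, "mean_degree": float(np.mean(degs)),
                                 "n_nodes": len(degs)})
    out = {
        "cross_species_curves": pd.DataFrame(curves),
        "cs_public": pd.DataFrame(sorted(cs), columns=["cdr3_aa"]),
        "category_degree": pd.DataFrame(cat_rows),
        "intersection_size": len(shmod.cross_species_sharing(mouse, human).intersection),
    }
    if outdir:
        _write_tables({k: v for k, v in out.items() if isinstance(v, pd.DataFrame)},
                      outdir, "fig2")
    return out


def run_figure5(cohorts: dict[str, Cohort], reference: Cohort,
                n: int = 1000, outdir=None) -> dict:
    """Per-individual Gini vs clustered-node counts across conditions, plus
    top-N frequency-by-sharing profiles."""
    ref_table = shmod.sharing_levels(reference)
    gini_rows, profile_rows = [], []
    for condition, cohort in cohorts.items():
        for rep in cohort:
            size = min(n, len(rep))
            sub = top_n(rep, size)
            net = netmod.build_network(sub.sequences)
            cn, ec = _net_summary(net)
            g = repertoire_gini(rep, top=size)
            gini_rows.append({"condition": condition, "individual": rep.individual_id,
                              "gini": g.coefficient, "clustered_nodes": cn, "edges": ec})
            for s, f in shmod.frequency_by_sharing_profile(sub, ref_table).items():
                profile_rows.append({"condition": condition,
                                     "individual": rep.individual_id,
                                     "sharing": s, "frequency": f})
    out = {"gini_vs_clustered": pd.DataFrame(gini_rows),
           "sharing_profile": pd.DataFrame(profile_rows)}
    if outdir:
        _write_tables(out, outdir, "fig5")
    return out


def _write_tables(tables: dict, outdir, prefix: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"prefix": prefix, "written": [], "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    for name, df in tables.items():
        path = outdir / f"{prefix}_{name}.csv"
        df.to_csv(path, index=False)
        manifest["written"].append(path.name)
    with open(outdir / f"{prefix}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
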