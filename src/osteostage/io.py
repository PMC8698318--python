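"""Readers and writers for the pipeline's TSV/JSON interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_concentrations", "write_concentrations",
    "read_isotopologues", "read_de_table", "read_prior", "read_gene_list",
    "read_tpm", "write_rate_panel", "write_changepoints",
    "write_phase_summaries", "write_regulons", "write_activity",
    "write_network_sif", "write_network_graphml",
]


def _require(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def read_concentrations(path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t")
    df = df.rename(columns={"concentration_mmol_per_l": "concentration"})
    return df


def write_concentrations(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"concentration": "concentration_mmol_per_l"})
    out.to_csv(path, sep="\t", index=False)


def read_isotopologues(path) -> pd.DataFrame:
    return pd.read_csv(_require(path), sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(_require(path), sep="\t")


def read_tpm(path) -> pd.DataFrame:
    return pd.read_csv(_require(path), sep="\t", index_col=0)


def read_prior(path, min_confidence: str | None = None) -> dict:
    """Read a regulator->target prior table into ``{regulator: set}``.

    An optional ``confidence`` column (DoRothEA-like classes A-E) can be
    filtered with ``min_confidence`` (e.g. ``"C"`` keeps A, B, C).
    """
    df = pd.read_csv(_require(path), sep="\t")
    if min_confidence is not None and "confidence" in df.columns:
        df = df[df["confidence"] <= min_confidence]
    return {reg: set(sub["target"]) for reg, sub in df.groupby("regulator")}


def read_gene_list(path) -> list:
    with open(_require(path)) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_rate_panel(panel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t")


def write_changepoints(result, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "change_days": result.change_days,
            "p_values": result.p_values,
            "phases": [{"phase": p, "start_day": s, "end_day": e}
                       for p, s, e in result.phases],
        }, fh, indent=1)


def write_phase_summaries(summaries, path) -> None:
    rows = []
    for s in summaries:
        for m in s.mean_rates:
            rows.append({
                "phase": s.phase, "start_day": s.start_day,
                "end_day": s.end_day, "metabolite": m,
                "mean_rate": s.mean_rates[m], "sem": s.sem_rates[m],
            })
        for name, value in s.flux_ratios.items():
            rows.append({
                "phase": s.phase, "start_day": s.start_day,
                "end_day": s.end_day, "metabolite": f"ratio:{name}",
                "mean_rate": value, "sem": float("nan"),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_regulons(regulons, path) -> None:
    pd.DataFrame([{
        "name": r.name, "regulator": r.regulator,
        "n_targets": len(r.targets), "targets": ",".join(r.targets),
        "correlation": r.correlation, "direction": r.direction,
    } for r in regulons]).to_csv(path, sep="\t", index=False)


def write_activity(regulons, path) -> None:
    pd.DataFrame({r.name: r.activity for r in regulons}).T.to_csv(
        path, sep="\t")


def write_network_sif(G: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in G.edges:
            fh.write(f"{a}\tregulates\t{b}\n")
        for node in G.nodes:
            if G.degree(node) == 0:
                fh.write(f"{node}\n")


def write_network_graphml(G: nx.DiGraph, path) -> None:
    nx.write_graphml(G, path)
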