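"""ceRNA network assembly: join mimic sites and cleavage sites into
lncRNA-miRNA-mRNA competition triples and compute network statistics.

A competition triple (l, m, g) exists whenever an accepted mimic site binds
lncRNA l to miRNA m and an accepted cleavage site binds m to mRNA g: the
lncRNA then competes with the mRNA for the shared miRNA. The network is a
typed tripartite graph with ``mimic`` (lncRNA-miRNA) and ``targeting``
(miRNA-mRNA) edges; ``competition`` (lncRNA-mRNA) edges are derived from
the triples, never stored independently, so every competition edge is
witnessed by at least one triple by construction.

The packaged fixture ``salt_stress_subnetwork.tsv`` transcribes a published
salt-stress ceRNA subnetwork from sweet sorghum roots (salt-tolerant and
salt-sensitive lines) and serves as a small worked example.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class CernaTriple:
    """One (lncRNA, miRNA, mRNA) competition record."""

    lncrna: str
    mirna: str
    mrna: str
    lncrna_de_call: str = "ns"
    mrna_de_call: str = "ns"
    subnetwork: str = ""

    def __post_init__(self) -> None:
        ids = (self.lncrna, self.mirna, self.mrna)
        if len(set(ids)) != 3:
            raise ValueError(f"triple ids must be distinct, got {ids}")


@dataclass
class CeRNANetwork:
    triples: List[CernaTriple]

    @property
    def lncrnas(self) -> Set[str]:
        return {t.lncrna for t in self.triples}

    @property
    def mirnas(self) -> Set[str]:
        return {t.mirna for t in self.triples}

    @property
    def mrnas(self) -> Set[str]:
        return {t.mrna for t in self.triples}

    def to_graph(self) -> nx.Graph:
        """Typed tripartite graph (nodes carry ``nodetype``, edges
        ``edgetype``); competition edges are derived from the triples."""
        g = nx.Graph()
        for t in self.triples:
            g.add_node(t.lncrna, nodetype="lncRNA", de_call=t.lncrna_de_call)
            g.add_node(t.mirna, nodetype="miRNA")
            g.add_node(t.mrna, nodetype="mRNA", de_call=t.mrna_de_call)
            g.add_edge(t.lncrna, t.mirna, edgetype="mimic")
            g.add_edge(t.mirna, t.mrna, edgetype="targeting")
            g.add_edge(t.lncrna, t.mrna, edgetype="competition")
        return g


@dataclass
class NetworkParams:
    require_lncrna_de: bool = False
    require_mrna_de: bool = False


def _accepted_pairs(
    sites, id_a: str, id_b: str
) -> List[Tuple[str, str]]:
    """Normalise a site table / site-object list to accepted (a, b) pairs."""
    if isinstance(sites, pd.DataFrame):
        acc = (
            sites[sites["accepted"].astype(bool)]
            if "accepted" in sites
            else sites
        )
        return list(
            dict.fromkeys(zip(acc[id_a].astype(str), acc[id_b].astype(str)))
        )
    pairs = []
    for s in sites:
        d = getattr(s, "duplex", s)
        if getattr(s, "accepted", d.accepted):
            pairs.append((d.mirna_id, d.target_id))
    if id_a == "target":  # caller wants (target, mirna) orientation
        pairs = [(b, a) for a, b in pairs]
    return list(dict.fromkeys(pairs))


def build_network(
    etm_sites,
    cleavage_sites,
    de_lnc: Optional[pd.DataFrame] = None,
    de_mrna: Optional[pd.DataFrame] = None,
    params: NetworkParams | None = None,
) -> CeRNANetwork:
    """Join accepted mimic and cleavage sites on the shared miRNA.

    ``etm_sites``/``cleavage_sites`` may be site DataFrames (as written by
    :mod:`cerna.mimic`) or lists of site objects. When DE tables (indexed by
    transcript id with a ``call`` column) are supplied, every site id must
    be present in them — dangling ids raise — and calls are annotated on
    the triples; ``params.require_lncrna_de`` keeps only triples whose
    lncRNA call is not ``ns``.
    """
    params = params or NetworkParams()
    mimic_pairs = _accepted_pairs(etm_sites, "target", "mirna")
    target_pairs = _accepted_pairs(cleavage_sites, "mirna", "target")

    def check_known(ids: Iterable[str], de: Optional[pd.DataFrame], what: str):
        if de is None:
            return
        missing = sorted(set(ids) - set(de.index.astype(str)))
        if missing:
            raise ValueError(
                f"{what} ids missing from the DE table: {missing}"
            )

    check_known((l for l, _ in mimic_pairs), de_lnc, "lncRNA")
    check_known((g for _, g in target_pairs), de_mrna, "mRNA")

    def call(de: Optional[pd.DataFrame], tid: str) -> str:
        if de is None:
            return "ns"
        return str(de.loc[tid, "call"])

    by_mirna: Dict[str, List[str]] = {}
    for mir, gene in target_pairs:
        by_mirna.setdefault(mir, []).append(gene)

    triples = []
    for lnc, mir in mimic_pairs:
        lnc_call = call(de_lnc, lnc)
        if params.require_lncrna_de and lnc_call == "ns":
            continue
        for gene in by_mirna.get(mir, []):
            mrna_call = call(de_mrna, gene)
            if params.require_mrna_de and mrna_call == "ns":
                continue
            triples.append(
                CernaTriple(lnc, mir, gene, lnc_call, mrna_call)
            )
    return CeRNANetwork(triples)


def network_stats(net: CeRNANetwork) -> dict:
    """Deterministic summary: node counts by type, edge counts, degrees."""
    mimic_edges = sorted({(t.lncrna, t.mirna) for t in net.triples})
    targeting_edges = sorted({(t.mirna, t.mrna) for t in net.triples})
    competition_edges = sorted({(t.lncrna, t.mrna) for t in net.triples})
    degree: Dict[str, int] = {}
    for a, b in [*mimic_edges, *targeting_edges]:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    per_mirna = {
        m: len({t.mrna for t in net.triples if t.mirna == m})
        for m in sorted(net.mirnas)
    }
    by_subnetwork: Dict[str, int] = {}
    for sub in sorted({t.subnetwork for t in net.triples if t.subnetwork}):
        by_subnetwork[sub] = len(
            {t.lncrna for t in net.triples if t.subnetwork == sub}
        )
    return {
        "n_lncrna": len(net.lncrnas),
        "n_mirna": len(net.mirnas),
        "n_mrna": len(net.mrnas),
        "n_triples": len(net.triples),
        "n_mimic_edges": len(mimic_edges),
        "n_targeting_edges": len(targeting_edges),
        "n_competition_edges": len(competition_edges),
        "degree": dict(sorted(degree.items())),
        "mirna_competed_gene_counts": per_mirna,
        "lncrnas_by_subnetwork": by_subnetwork,
    }


_TRIPLE_COLUMNS = [
    "lncrna",
    "mirna",
    "mrna",
    "lncrna_de_call",
    "mrna_de_call",
    "subnetwork",
]


def write_triples_tsv(net: CeRNANetwork, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lncrna": t.lncrna,
                "mirna": t.mirna,
                "mrna": t.mrna,
                "lncrna_de_call": t.lncrna_de_call,
                "mrna_de_call": t.mrna_de_call,
                "subnetwork": t.subnetwork,
            }
            for t in net.triples
        ],
        columns=_TRIPLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def load_triples_tsv(path: str | Path) -> CeRNANetwork:
    df = pd.read_csv(path, sep="\t").fillna("")
    triples = [
        CernaTriple(
            lncrna=str(r["lncrna"]),
            mirna=str(r["mirna"]),
            mrna=str(r["mrna"]),
            lncrna_de_call=str(r.get("lncrna_de_call", "ns") or "ns"),
            mrna_de_call=str(r.get("mrna_de_call", "ns") or "ns"),
            subnetwork=str(r.get("subnetwork", "") or ""),
        )
        for _, r in df.iterrows()
    ]
    return CeRNANetwork(triples)


def write_graphml(net: CeRNANetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_graph(), str(path))


def load_salt_stress_example() -> CeRNANetwork:
    """The packaged sweet-sorghum salt-stress ceRNA subnetwork fixture."""
    ref = resources.files("cerna.data").joinpath("salt_stress_subnetwork.tsv")
    with resources.as_file(ref) as path:
        return load_triples_tsv(path)
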