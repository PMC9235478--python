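"""Collapsing shared SNPs into loci and building the trait network.

Nearby significant SNPs tag the same association signal, so shared SNPs
are greedily clumped into loci around lead SNPs (best theta q-value
first) within a positional window, and trait relationships are
summarized as a weighted graph: nodes are traits, an edge's weight sums,
over the pair's shared loci, the inverse of the number of traits the
locus lead is associated with -- a SNP shared by many traits probably
tags a generic process and is down-weighted accordingly.

Clumping here is purely positional (no LD weighting); a precomputed
pairwise-LD table can be supplied to additionally absorb SNPs in LD with
the lead beyond the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "TraitNetwork",
    "positional_clump",
    "build_network",
    "collapse_to_domains",
    "write_loci_bed",
    "write_network_tsv",
]


@dataclass
class Locus:
    """A clumped genomic region of shared SNPs (1-based closed interval)."""

    chrom: str
    start: int
    end: int
    lead_id: str
    member_ids: list

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("locus start must be <= end")
        if self.lead_id not in self.member_ids:
            raise ValueError("lead must be a member of its locus")


@dataclass
class TraitNetwork:
    """Weighted undirected trait graph.

    ``edges`` maps frozenset({trait_a, trait_b}) -> dict(weight, n_loci).
    """

    nodes: set = field(default_factory=set)
    edges: dict = field(default_factory=dict)

    def add_edge(self, a: str, b: str, weight: float, n_loci: int) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        if weight < 0:
            raise ValueError("edge weights must be >= 0")
        self.nodes.update((a, b))
        key = frozenset((a, b))
        if key in self.edges:
            self.edges[key]["weight"] += weight
            self.edges[key]["n_loci"] += n_loci
        else:
            self.edges[key] = {"weight": weight, "n_loci": n_loci}

    def weight(self, a: str, b: str) -> float:
        e = self.edges.get(frozenset((a, b)))
        return e["weight"] if e else 0.0

    def to_networkx(self):
        """Convert to a networkx.Graph (weight and n_loci edge attributes)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for key, attrs in self.edges.items():
            a, b = sorted(key)
            g.add_edge(a, b, **attrs)
        return g


def positional_clump(
    results: pd.DataFrame,
    window_kb: float = 5000.0,
    q_threshold: float = 0.05,
    ld_table: pd.DataFrame | None = None,
    ld_r2: float = 0.2,
) -> list[Locus]:
    """Greedy positional clumping of shared SNPs into loci.

    Shared-flagged SNPs are sorted by q_theta ascending (ties by p_theta,
    then chromosome and position); the best unassigned SNP becomes a
    lead and absorbs all unassigned shared SNPs within ``window_kb`` on
    the same chromosome.  When an ``ld_table`` (columns id_a, id_b, r2)
    is given, SNPs in LD >= ``ld_r2`` with the lead are absorbed as well,
    regardless of distance.  Deterministic.
    """
    need = {"id", "chrom", "pos", "q_theta", "p_theta", "shared_flag"}
    missing = need - set(results.columns)
    if missing:
        raise ValueError(f"results table lacks columns: {sorted(missing)}")
    df = results[results["shared_flag"] & (results["q_theta"] < q_threshold)]
    if df.empty:
        return []
    df = df.sort_values(
        ["q_theta", "p_theta", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)

    ld_partners: dict[str, set] = {}
    if ld_table is not None:
        strong = ld_table[ld_table["r2"] >= ld_r2]
        for a, b in zip(strong["id_a"], strong["id_b"]):
            ld_partners.setdefault(a, set()).add(b)
            ld_partners.setdefault(b, set()).add(a)

    window = int(window_kb * 1000)
    ids = df["id"].to_numpy()
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    assigned = np.zeros(len(df), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(df)):
        if assigned[i]:
            continue
        near = (
            ~assigned
            & (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if ld_partners:
            in_ld = np.isin(ids, list(ld_partners.get(ids[i], ())))
            near |= ~assigned & in_ld
        members = np.flatnonzero(near)
        assigned[members] = True
        loci.append(
            Locus(
                chrom=str(chroms[i]),
                start=int(pos[members].min()),
                end=int(pos[members].max()),
                lead_id=str(ids[i]),
                member_ids=[str(x) for x in ids[members]],
            )
        )
    return loci


def build_network(
    pairwise_loci: dict,
    snp_trait_counts: dict | None = None,
) -> TraitNetwork:
    """Assemble the weighted trait network from per-pair locus lists.

    Parameters
    ----------
    pairwise_loci : dict
        (trait_a, trait_b) -> list of Locus from that pair's run.
    snp_trait_counts : dict, optional
        variant id -> number of traits the SNP is associated with.  When
        omitted, it is derived from the pairwise results themselves
        (traits in whose pairs the lead appears).  Each locus contributes
        1 / count to its pair's edge weight.
    """
    if snp_trait_counts is None:
        traits_of: dict[str, set] = {}
        for (a, b), loci in pairwise_loci.items():
            for locus in loci:
                traits_of.setdefault(locus.lead_id, set()).update((a, b))
        snp_trait_counts = {k: len(v) for k, v in traits_of.items()}

    net = TraitNetwork()
    for (a, b), loci in pairwise_loci.items():
        net.nodes.update((a, b))
        if not loci:
            continue
        weight = 0.0
        for locus in loci:
            count = snp_trait_counts.get(locus.lead_id, 2)
            if count < 1:
                raise ValueError(f"trait count < 1 for {locus.lead_id}")
            weight += 1.0 / count
        net.add_edge(a, b, weight=weight, n_loci=len(loci))
    return net


def collapse_to_domains(net: TraitNetwork, domain_map: dict) -> TraitNetwork:
    """Collapse the trait network to trait domains.

    A domain edge exists iff any underlying trait-pair edge exists; its
    weight is the sum of the constituent weights.
    """
    unmapped = net.nodes - set(domain_map)
    if unmapped:
        raise ValueError(f"traits without a domain: {sorted(unmapped)}")
    out = TraitNetwork()
    out.nodes.update(domain_map[t] for t in net.nodes)
    for key, attrs in net.edges.items():
        a, b = sorted(key)
        da, db = domain_map[a], domain_map[b]
        if da == db:
            continue
        out.add_edge(da, db, weight=attrs["weight"], n_loci=attrs["n_loci"])
    return out


def write_loci_bed(loci: list, path) -> None:
    """Write loci as BED-like TSV (half-open start, 0-based)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlead_id\tn_members\n")
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.lead_id}\t{len(locus.member_ids)}\n"
            )


def write_network_tsv(net: TraitNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("trait_a\ttrait_b\tweight\tn_loci\n")
        for key in sorted(net.edges, key=lambda k: tuple(sorted(k))):
            a, b = sorted(key)
            e = net.edges[key]
            fh.write(f"{a}\t{b}\t{e['weight']!r}\t{e['n_loci']}\n")
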