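"""Hit-table-derived classifications.

This module turns raw similarity-search results into the orthology and
homology labels the comparative analysis rests on:

* reciprocal best hits (RBH) between two proteomes — the standard ortholog
  proxy,
* ORFan / meta-ORFan / homolog labels from reference-database and
  environmental-database searches,
* duplicated-gene clusters from a proteome-vs-itself search,
* family (COG/NCVOG) assignment from hits against a family database,
* the homolog acceptance filter (minimum alignment length and identity).

"Best" is always decided by smallest e-value, ties broken by larger bitscore,
then lexicographically smallest subject id, so results are deterministic under
any input ordering.  Default e-value cutoffs are carried by
:class:`ThresholdConfig`: 1e-5 for RBH and ORFan calls, 1e-10 for duplicates,
1e-3 for family assignment, 1e-100 for the high-grade synteny subset, and the
acceptance filter of >70 aligned residues and >20% identity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import HitRecord

HOMOLOG = "HOMOLOG"
ORFAN = "ORFAN"
META_ORFAN = "META_ORFAN"


@dataclass(frozen=True)
class ThresholdConfig:
    """E-value cutoffs and homolog acceptance filter used across the pipeline."""

    e_rbh: float = 1e-5
    e_dup: float = 1e-10
    e_family: float = 1e-3
    e_synteny_grade: float = 1e-100
    min_aln_len: int = 70
    min_pid: float = 20.0

    def __post_init__(self) -> None:
        for name in ("e_rbh", "e_dup", "e_family", "e_synteny_grade"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in (0, 1]")
        if self.min_aln_len < 0 or self.min_pid < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit ortholog pair between two proteomes."""

    a_id: str
    b_id: str
    evalue_ab: float
    evalue_ba: float
    min_bitscore: float


@dataclass(frozen=True)
class HomologyLabel:
    protein_id: str
    label: str  # HOMOLOG | ORFAN | META_ORFAN


def _best_key(hit: HitRecord) -> tuple[float, float, str]:
    return (hit.evalue, -hit.bitscore, hit.subject_id)


def best_hit_records(
    hits: Iterable[HitRecord], e_max: float
) -> dict[str, HitRecord]:
    """Best qualifying hit per query (e-value, then bitscore, then subject id)."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > e_max:
            continue
        cur = best.get(h.query_id)
        if cur is None or _best_key(h) < _best_key(cur):
            best[h.query_id] = h
    return best


def best_hits(hits: Iterable[HitRecord], e_max: float) -> dict[str, str]:
    """Map each query with a qualifying hit to its best subject."""
    return {q: h.subject_id for q, h in best_hit_records(hits, e_max).items()}


def rbh_pairs(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    e_max: float = 1e-5,
) -> set[OrthologPair]:
    """Reciprocal best hits between two proteomes.

    ``(a, b)`` is returned iff ``a``'s best subject in the A→B table is ``b``
    and ``b``'s best subject in the B→A table is ``a``, both at e-value
    <= ``e_max``.  The operation is symmetric in the two tables up to the
    obvious relabelling of directions.
    """
    ab = best_hit_records(hits_ab, e_max)
    ba = best_hit_records(hits_ba, e_max)
    pairs: set[OrthologPair] = set()
    for a, hit_ab in ab.items():
        b = hit_ab.subject_id
        hit_ba = ba.get(b)
        if hit_ba is not None and hit_ba.subject_id == a:
            pairs.add(
                OrthologPair(
                    a_id=a,
                    b_id=b,
                    evalue_ab=hit_ab.evalue,
                    evalue_ba=hit_ba.evalue,
                    min_bitscore=min(hit_ab.bitscore, hit_ba.bitscore),
                )
            )
    return pairs


def classify_orfans(
    protein_ids: Iterable[str],
    hits_vs_refdb: Iterable[HitRecord],
    hits_vs_envdb: Iterable[HitRecord],
    e_max: float = 1e-5,
) -> tuple[list[HomologyLabel], dict[str, float]]:
    """Label every protein HOMOLOG, META_ORFAN or ORFAN.

    A protein with any reference-database hit at e-value <= ``e_max`` is a
    HOMOLOG; otherwise, if it has a qualifying hit in the environmental
    database it is a META_ORFAN; otherwise it is an ORFAN.  Returns the labels
    (one per protein, in sorted protein order) and the fraction of each label.
    """
    ids = sorted(set(protein_ids))
    id_set = set(ids)
    ref_hit: set[str] = set()
    env_hit: set[str] = set()
    for h in hits_vs_refdb:
        if h.query_id not in id_set:
            raise ValueError(f"refdb hit query {h.query_id!r} not in protein set")
        if h.evalue <= e_max:
            ref_hit.add(h.query_id)
    for h in hits_vs_envdb:
        if h.query_id not in id_set:
            raise ValueError(f"envdb hit query {h.query_id!r} not in protein set")
        if h.evalue <= e_max:
            env_hit.add(h.query_id)
    labels = []
    for p in ids:
        if p in ref_hit:
            lab = HOMOLOG
        elif p in env_hit:
            lab = META_ORFAN
        else:
            lab = ORFAN
        labels.append(HomologyLabel(p, lab))
    n = len(ids)
    fractions = {
        lab: (sum(1 for x in labels if x.label == lab) / n if n else 0.0)
        for lab in (HOMOLOG, META_ORFAN, ORFAN)
    }
    return labels, fractions


def find_duplicates(
    self_hits: Iterable[HitRecord], e_max: float = 1e-10
) -> set[frozenset[str]]:
    """Duplicated-gene clusters from a proteome-vs-itself search.

    Hits with query != subject and e-value <= ``e_max`` define an undirected
    graph; connected components of size >= 2 are the duplicate clusters.
    """
    g = nx.Graph()
    for h in self_hits:
        if h.query_id != h.subject_id and h.evalue <= e_max:
            g.add_edge(h.query_id, h.subject_id)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}


def duplicated_genes(self_hits: Iterable[HitRecord], e_max: float = 1e-10) -> set[str]:
    """The set of proteins belonging to any duplicate cluster."""
    return {p for cluster in find_duplicates(self_hits, e_max) for p in cluster}


def assign_families(
    hits_vs_family_db: Iterable[HitRecord],
    subject_to_family: Mapping[str, str],
    e_max: float = 1e-3,
) -> pd.DataFrame:
    """Assign each protein the family of its best qualifying database hit.

    Ties on e-value are broken by larger bitscore, then lexicographic family
    id, then subject id.  Proteins with no qualifying hit are omitted.  A
    qualifying hit whose subject has no family mapping is an error.
    """
    best: dict[str, tuple[tuple[float, float, str, str], HitRecord, str]] = {}
    missing: set[str] = set()
    for h in hits_vs_family_db:
        if h.evalue > e_max:
            continue
        fam = subject_to_family.get(h.subject_id)
        if fam is None:
            missing.add(h.subject_id)
            continue
        key = (h.evalue, -h.bitscore, fam, h.subject_id)
        cur = best.get(h.query_id)
        if cur is None or key < cur[0]:
            best[h.query_id] = (key, h, fam)
    if missing:
        raise KeyError(
            "subjects with no family mapping: " + ", ".join(sorted(missing))
        )
    rows = [
        (q, fam, hit.evalue)
        for q, (_, hit, fam) in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["protein_id", "family_id", "evalue"])


def filter_homolog_candidates(
    hits: Iterable[HitRecord], min_len: int = 70, min_pid: float = 20.0
) -> list[HitRecord]:
    """Keep hits with alignment length > ``min_len`` AND identity > ``min_pid``.

    Both inequalities are strict: a 70-residue alignment or a 20%-identity hit
    is rejected.
    """
    return [h for h in hits if h.aln_length > min_len and h.pct_identity > min_pid]


def dedupe_best_hsp(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Collapse multiple HSPs per (query, subject) to the single best record."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or _best_key(h) < _best_key(cur):
            best[key] = h
    return list(best.values())
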