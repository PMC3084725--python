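"""Synteny detection between two genomes from ortholog pairs.

A synteny block is a run of at least two orthologous gene pairs that are
consecutive (up to a configurable rank gap) in both genomes, in the same
order (collinear) or in exactly reversed order (inverted).  Synteny is
defined on gene *ranks*, not nucleotide coordinates, so blocks are robust to
intergenic-length differences.  Pairs are first filtered to high-grade
orthologs (``max(evalue_ab, evalue_ba) <= e_max``, default 1e-100).

:func:`dotplot_points` exports the classic ortholog dot-plot (gene midpoint
in genome A vs genome B, coloured by score) without any block structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .homology import OrthologPair
from .io_formats import Genome

COLLINEAR = "collinear"
INVERTED = "inverted"


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal run of >=2 consecutive ortholog pairs in consistent order."""

    pairs: tuple[tuple[int, int], ...]  # (rank_a, rank_b), rank_a increasing
    orientation: str  # collinear | inverted
    genes: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)


def _anchor_points(
    pairs: Iterable[OrthologPair], genome_a: Genome, genome_b: Genome
) -> list[tuple[int, int, str, str, OrthologPair]]:
    rank_a = genome_a.rank_of()
    rank_b = genome_b.rank_of()
    pts = []
    for p in pairs:
        if p.a_id not in rank_a:
            raise ValueError(f"pair references unknown gene {p.a_id!r} in {genome_a.genome_id}")
        if p.b_id not in rank_b:
            raise ValueError(f"pair references unknown gene {p.b_id!r} in {genome_b.genome_id}")
        pts.append((rank_a[p.a_id], rank_b[p.b_id], p.a_id, p.b_id, p))
    pts.sort(key=lambda t: t[0])
    return pts


def synteny_blocks(
    pairs: Iterable[OrthologPair],
    genome_a: Genome,
    genome_b: Genome,
    e_max: float = 1e-100,
    gap: int = 0,
) -> list[SyntenyBlock]:
    """Maximal runs of consecutive retained ortholog pairs.

    Retained pairs (both e-values <= ``e_max``) are sorted by rank in genome
    A.  A run extends from one retained pair to the next when the rank-A step
    is at most ``gap + 1`` and the rank-B step has magnitude at most
    ``gap + 1`` with a sign consistent with the run's orientation (set by its
    first step).  Runs are grown greedily left to right, so blocks never
    overlap in rank A; runs of length 1 are discarded.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    retained = [p for p in pairs if max(p.evalue_ab, p.evalue_ba) <= e_max]
    pts = _anchor_points(retained, genome_a, genome_b)
    blocks: list[SyntenyBlock] = []
    i = 0
    step = gap + 1
    while i < len(pts):
        run = [pts[i]]
        sign = 0
        j = i + 1
        while j < len(pts):
            da = pts[j][0] - run[-1][0]
            db = pts[j][1] - run[-1][1]
            if da > step or abs(db) > step or db == 0:
                break
            s = 1 if db > 0 else -1
            if sign and s != sign:
                break
            sign = s
            run.append(pts[j])
            j += 1
        if len(run) >= 2:
            blocks.append(
                SyntenyBlock(
                    pairs=tuple((ra, rb) for ra, rb, *_ in run),
                    orientation=COLLINEAR if sign > 0 else INVERTED,
                    genes=tuple((ga, gb) for _, _, ga, gb, _ in run),
                )
            )
            i = j
        else:
            i += 1
    return blocks


def dotplot_points(
    pairs: Iterable[OrthologPair],
    genome_a: Genome,
    genome_b: Genome,
    score: str = "evalue",
    e_max: float | None = None,
) -> pd.DataFrame:
    """One row per ortholog pair: gene midpoints in both genomes plus a score.

    ``score`` is either ``evalue`` (the worse of the two directions) or
    ``bitscore`` (the pair's minimum bitscore).  ``e_max``, when given,
    filters pairs on the worse e-value; no other filtering is applied.
    """
    if score not in ("evalue", "bitscore"):
        raise ValueError("score must be 'evalue' or 'bitscore'")
    by_id_a = genome_a.feature_by_id()
    by_id_b = genome_b.feature_by_id()
    rows = []
    for p in pairs:
        worst_e = max(p.evalue_ab, p.evalue_ba)
        if e_max is not None and worst_e > e_max:
            continue
        if p.a_id not in by_id_a:
            raise ValueError(f"pair references unknown gene {p.a_id!r} in {genome_a.genome_id}")
        if p.b_id not in by_id_b:
            raise ValueError(f"pair references unknown gene {p.b_id!r} in {genome_b.genome_id}")
        value = worst_e if score == "evalue" else p.min_bitscore
        rows.append(
            (p.a_id, p.b_id, by_id_a[p.a_id].midpoint, by_id_b[p.b_id].midpoint, value)
        )
    rows.sort(key=lambda r: (r[2], r[3]))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "midpoint_a", "midpoint_b", score]
    )


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Flatten blocks to a long table (block index, orientation, ranks, genes)."""
    rows = []
    for i, blk in enumerate(blocks):
        for (ra, rb), (ga, gb) in zip(blk.pairs, blk.genes):
            rows.append((i, blk.orientation, ra, rb, ga, gb))
    return pd.DataFrame(
        rows, columns=["block", "orientation", "rank_a", "rank_b", "gene_a", "gene_b"]
    )
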