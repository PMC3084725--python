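"""Positional analysis of gene categories along a linear genome.

Genes are classified as TERMINAL (midpoint within the first or last ``window``
nucleotides of the sequenced fragment, 50 kb by default) or CENTRAL, a 2x2
contingency table of category x region is built, and enrichment is tested
with a two-sided Fisher exact test implemented directly on the hypergeometric
distribution with log-factorials.

Genes are classified by their integer midpoint so a gene spanning the window
boundary belongs to exactly one region; the boundary itself is inclusive on
the terminal side.  Strand is ignored throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Set

import pandas as pd

from .io_formats import GeneFeature, Genome

TERMINAL = "TERMINAL"
CENTRAL = "CENTRAL"

_LABEL_RE = re.compile(r"^(RBH:.+|DUPLICATED|ORFAN|META_ORFAN|COG:.+|NCVOG|CORE)$")


@dataclass(frozen=True)
class RegionSpec:
    """Terminal-window geometry of a linear genome fragment."""

    genome_length: int
    window: int = 50_000

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if 2 * self.window >= self.genome_length:
            raise ValueError(
                f"2*window ({2 * self.window}) must be smaller than the genome "
                f"length ({self.genome_length})"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows {in-category, not}, columns {terminal, central}.

    ``a`` = in-category & terminal, ``b`` = in-category & central,
    ``c`` = not-in-category & terminal, ``d`` = not-in-category & central.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-region category percentages, odds ratio, and exact two-sided p."""

    rate_terminal: float
    rate_central: float
    odds_ratio: float
    p_two_sided: float
    table: ContingencyTable


def classify_region(feature: GeneFeature, spec: RegionSpec) -> str:
    """TERMINAL iff the gene midpoint lies in ``[1, W]`` or ``(L - W, L]``."""
    if feature.end > spec.genome_length:
        raise ValueError(
            f"gene {feature.gene_id!r} ends at {feature.end}, beyond genome "
            f"length {spec.genome_length}"
        )
    mid = feature.midpoint
    if mid <= spec.window or mid > spec.genome_length - spec.window:
        return TERMINAL
    return CENTRAL


def contingency(
    genome: Genome, in_category: Set[str], spec: RegionSpec
) -> ContingencyTable:
    """Cross-tabulate category membership x region over every gene."""
    known = set(genome.gene_ids())
    unknown = set(in_category) - known
    if unknown:
        raise ValueError(
            "category contains unknown gene ids: " + ", ".join(sorted(unknown))
        )
    a = b = c = d = 0
    for f in genome.features:
        terminal = classify_region(f, spec) == TERMINAL
        if f.gene_id in in_category:
            if terminal:
                a += 1
            else:
                b += 1
        else:
            if terminal:
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


@lru_cache(maxsize=None)
def _lfact(n: int) -> float:
    return math.lgamma(n + 1)


def _log_hypergeom_pmf(k: int, n: int, r: int, c: int) -> float:
    # P(K = k) with K ~ Hypergeometric(N=n, successes=c, draws=r)
    return (
        _lfact(c)
        - _lfact(k)
        - _lfact(c - k)
        + _lfact(n - c)
        - _lfact(r - k)
        - _lfact(n - c - r + k)
        - (_lfact(n) - _lfact(r) - _lfact(n - r))
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Conditioning on both margins, the count ``a`` follows a hypergeometric
    distribution; the two-sided p-value sums P(k) over every k in the support
    whose probability does not exceed that of the observed table (with a
    1e-12 relative guard against floating-point ties).  Computed with
    log-factorials, exact for all desk-scale tables.
    """
    if table.total == 0:
        raise ValueError("all-zero contingency table")
    n = table.total
    r = table.a + table.b  # in-category margin
    c = table.a + table.c  # terminal margin
    lo = max(0, r + c - n)
    hi = min(r, c)
    p_obs = math.exp(_log_hypergeom_pmf(table.a, n, r, c))
    threshold = p_obs * (1.0 + 1e-12)
    p = 0.0
    for k in range(lo, hi + 1):
        pk = math.exp(_log_hypergeom_pmf(k, n, r, c))
        if pk <= threshold:
            p += pk
    return min(p, 1.0)


def enrichment_from_table(table: ContingencyTable) -> EnrichmentResult:
    """Rates, odds ratio and exact p from an existing 2x2 table."""
    n_terminal = table.a + table.c
    n_central = table.b + table.d
    if n_terminal == 0:
        raise ValueError("terminal region contains no genes; rates undefined")
    if n_central == 0:
        raise ValueError("central region contains no genes; rates undefined")
    rate_t = 100.0 * table.a / n_terminal
    rate_c = 100.0 * table.b / n_central
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return EnrichmentResult(
        rate_terminal=rate_t,
        rate_central=rate_c,
        odds_ratio=odds,
        p_two_sided=fisher_exact_two_sided(table),
        table=table,
    )


def enrichment(
    genome: Genome, in_category: Set[str], spec: RegionSpec
) -> EnrichmentResult:
    """Terminal-vs-central enrichment of a gene category along the genome."""
    return enrichment_from_table(contingency(genome, in_category, spec))


def genome_tracks(
    genome: Genome, annotations: Mapping[str, Set[str]]
) -> pd.DataFrame:
    """One row per gene with position, strand and all annotation labels.

    Labels must come from the declared vocabulary (``RBH:<taxon>``,
    ``DUPLICATED``, ``ORFAN``, ``META_ORFAN``, ``COG:<cat>``, ``NCVOG``,
    ``CORE``); each distinct label becomes a 0/1 column, so the table is
    directly plottable as genome-map tracks.
    """
    known = set(genome.gene_ids())
    unknown = set(annotations) - known
    if unknown:
        raise ValueError(
            "annotations reference unknown gene ids: " + ", ".join(sorted(unknown))
        )
    all_labels: set[str] = set()
    for labels in annotations.values():
        for lab in labels:
            if not _LABEL_RE.match(lab):
                raise ValueError(f"label {lab!r} outside the declared vocabulary")
            all_labels.add(lab)
    label_cols = sorted(all_labels)
    rows = []
    for f in genome.features:
        labels = annotations.get(f.gene_id, set())
        rows.append(
            [f.gene_id, f.start, f.end, f.strand, f.midpoint]
            + [1 if lab in labels else 0 for lab in label_cols]
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "strand", "midpoint"] + label_cols
    )
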