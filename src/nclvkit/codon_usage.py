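"""Codon counting and relative synonymous codon usage (RSCU).

RSCU for codon *j* of an amino acid with a synonymous family of size *n* is

    RSCU_j = x_j / ((1/n) * sum_{j' in family} x_{j'})

i.e. the observed count divided by the count expected under uniform usage
within the family.  A value of 1 indicates unbiased usage.  The standard
genetic code (translation table 1) is fixed; stop codons are excluded from
the families; single-codon families (Met, Trp) have RSCU 1 whenever used.
Families with zero total count are reported as UNDEFINED (``None``) rather
than 0, distinguishing an unused family from an unused codon.

Genome-level RSCU pools codon counts across genes before applying the formula
once (it is not a per-gene average).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: amino acid -> tuple of synonymous codons (standard code, stops excluded)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = _TABLE.forward_table[_codon]
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_FAMILY_OF: dict[str, str] = {c: aa for aa, cs in SYNONYMOUS_FAMILIES.items() for c in cs}


@dataclass(frozen=True)
class CodonCounts:
    """In-frame codon counts of one or more coding sequences."""

    counts: Mapping[str, int]
    n_skipped: int = 0

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, x in other.counts.items():
            merged[c] = merged.get(c, 0) + x
        return CodonCounts(merged, self.n_skipped + other.n_skipped)


def codon_counts(cds: str) -> CodonCounts:
    """Count in-frame codons of a coding sequence (alphabet ACGTN).

    Triplets containing ``N`` are skipped and tallied in ``n_skipped``; an
    empty sequence or a length not divisible by 3 is an error.
    """
    seq = str(cds).upper().replace("U", "T")
    if not seq:
        raise ValueError("empty coding sequence")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    counts: dict[str, int] = {}
    skipped = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            skipped += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts, skipped)


def rscu(counts: CodonCounts) -> dict[str, float | None]:
    """RSCU per sense codon; ``None`` marks codons of unused families.

    Stop codons are ignored.  Within each synonymous family with a positive
    total the values sum to the family size.
    """
    values: dict[str, float | None] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                values[c] = None
            continue
        mean = total / len(codons)
        for c in codons:
            values[c] = counts.counts.get(c, 0) / mean
    return values


def genome_rscu(genes: Iterable[str]) -> dict[str, float | None]:
    """Pooled RSCU over a set of coding sequences.

    Codon counts are summed across all genes and the RSCU formula applied once
    to the pooled counts.  Per-gene errors are re-raised with the gene index.
    """
    pooled = CodonCounts({}, 0)
    n = 0
    for i, gene in enumerate(genes):
        try:
            pooled = pooled + codon_counts(gene)
        except ValueError as exc:
            raise ValueError(f"gene {i}: {exc}") from exc
        n += 1
    if n == 0:
        raise ValueError("no genes supplied")
    return rscu(pooled)


def rscu_table(values: Mapping[str, float | None]) -> "pd.DataFrame":
    """Long-format RSCU table (codon, amino acid, RSCU), sorted by amino acid."""
    import pandas as pd

    rows = [
        (codon, _FAMILY_OF[codon], values.get(codon))
        for codon in SENSE_CODONS
    ]
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "rscu"])
    return df.sort_values(["amino_acid", "codon"]).reset_index(drop=True)
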