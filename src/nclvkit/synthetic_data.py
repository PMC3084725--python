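"""Truth-known synthetic inputs for every stage of the analysis.

Each generator emulates the statistical structure one downstream stage
assumes, with the planted truth returned alongside the data so recovery can
be scored:

* :func:`gen_phyletic_profiles` — a binary taxa x family matrix with planted
  group structure (each group owns a distinct core block of families) and
  independent presence/absence flip noise,
* :func:`gen_annotated_genome` — non-overlapping gene intervals placed
  uniformly on a linear chromosome, with a gene category whose probability
  differs between the terminal windows and the centre,
* :func:`gen_hit_table` — mutual similarity hits consistent with a planted
  ortholog pairing, plus background decoy hits and optional spurious
  significant hits; true and decoy e-values straddle the 1e-5 cutoff so
  threshold logic is actually exercised,
* :func:`gen_coding_sequences` — coding sequences whose codons are drawn
  with caller-specified weights, giving closed-form expected RSCU values.

Every generator takes an explicit integer ``seed`` and uses one local
:class:`numpy.random.Generator`; identical seeds and parameters give
byte-identical outputs.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .codon_usage import SENSE_CODONS, STOP_CODONS
from .io_formats import GeneFeature, Genome, HitRecord, make_seq_record

CATEGORY_POSITIVE = "duplicated"
CATEGORY_NEGATIVE = "other"


@dataclass(frozen=True)
class PhyleticTruth:
    """Planted group structure behind a synthetic phyletic matrix."""

    group_of: Mapping[str, str]
    planted_matrix: pd.DataFrame

    def groups(self) -> list[set[str]]:
        """The planted partition as a list of taxon sets (sorted by smallest member)."""
        out: dict[str, set[str]] = {}
        for taxon, g in self.group_of.items():
            out.setdefault(g, set()).add(taxon)
        return sorted(out.values(), key=min)


@dataclass(frozen=True)
class GenomeTruth:
    """Planted gene categories and ortholog pairs behind synthetic genomes."""

    category_of: Mapping[str, str]
    planted_pairs: frozenset[tuple[str, str]] = frozenset()

    def positives(self) -> set[str]:
        return {g for g, c in self.category_of.items() if c == CATEGORY_POSITIVE}


# ---------------------------------------------------------------------------
# phyletic profiles
# ---------------------------------------------------------------------------


def gen_phyletic_profiles(
    n_groups: int,
    taxa_per_group: int,
    n_families: int,
    core_frac: float,
    flip_rate: float,
    seed: int,
) -> tuple[pd.DataFrame, PhyleticTruth]:
    """Binary matrix with one distinct core family block per group, plus noise.

    Each group receives a block of ``ceil(core_frac * n_families)`` families
    set to 1 for all its taxa; every other cell is 0.  Every cell is then
    independently flipped with probability ``flip_rate``.
    """
    if not 0.0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    if n_families < 1 or n_groups < 1 or taxa_per_group < 1:
        raise ValueError("n_groups, taxa_per_group and n_families must be >= 1")
    core = math.ceil(core_frac * n_families)
    if n_groups * core > n_families:
        raise ValueError(
            f"{n_groups} core blocks of {core} families exceed {n_families} families"
        )
    rng = np.random.default_rng(seed)
    taxa = [f"g{g + 1}_t{t + 1}" for g in range(n_groups) for t in range(taxa_per_group)]
    families = [f"fam{j:04d}" for j in range(n_families)]
    planted = np.zeros((len(taxa), n_families), dtype="int8")
    group_of: dict[str, str] = {}
    for g in range(n_groups):
        rows = slice(g * taxa_per_group, (g + 1) * taxa_per_group)
        planted[rows, g * core : (g + 1) * core] = 1
        for t in range(taxa_per_group):
            group_of[taxa[g * taxa_per_group + t]] = f"group{g + 1}"
    flips = rng.random(planted.shape) < flip_rate
    noisy = (planted ^ flips.astype("int8")).astype("int8")
    planted_df = pd.DataFrame(planted, index=taxa, columns=families)
    noisy_df = pd.DataFrame(noisy, index=taxa, columns=families)
    return noisy_df, PhyleticTruth(group_of=group_of, planted_matrix=planted_df)


# ---------------------------------------------------------------------------
# annotated genome with positional category bias
# ---------------------------------------------------------------------------


def gen_annotated_genome(
    length: int,
    n_genes: int,
    window: int,
    p_cat_terminal: float,
    p_cat_central: float,
    seed: int,
    gene_length_range: tuple[int, int] = (300, 600),
    max_retries: int = 1000,
    genome_id: str = "synthetic",
) -> tuple[Genome, GenomeTruth]:
    """Non-overlapping genes placed uniformly, with a terminally biased category.

    Each gene's length is uniform on ``gene_length_range``; placement is by
    rejection sampling (uniform start, resample on overlap, error after
    ``max_retries`` consecutive failures for one gene).  A gene is
    category-positive with probability ``p_cat_terminal`` when its midpoint
    falls within ``window`` of either fragment end, else ``p_cat_central``.
    """
    if 2 * window >= length:
        raise ValueError("2*window must be smaller than the genome length")
    lo, hi = gene_length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid gene length range")
    for name, p in (("p_cat_terminal", p_cat_terminal), ("p_cat_central", p_cat_central)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_genes * (lo + 1) > length:
        raise ValueError(f"cannot pack {n_genes} genes of >= {lo} nt into {length} nt")
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return Genome(genome_id, length, ()), GenomeTruth(category_of={})

    starts: list[int] = []  # sorted placed starts
    ends_by_start: dict[int, int] = {}
    intervals: list[tuple[int, int]] = []
    for _ in range(n_genes):
        glen = int(rng.integers(lo, hi + 1))
        placed = False
        for _attempt in range(max_retries):
            s = int(rng.integers(1, length - glen + 2))  # 1-based start
            e = s + glen - 1
            i = bisect.bisect_left(starts, s)
            if i > 0 and ends_by_start[starts[i - 1]] >= s:
                continue
            if i < len(starts) and starts[i] <= e:
                continue
            bisect.insort(starts, s)
            ends_by_start[s] = e
            intervals.append((s, e))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"gene placement failed after {max_retries} retries; "
                "genome too densely packed"
            )
    intervals.sort()
    strands = rng.choice(["+", "-"], size=n_genes)
    features = []
    category: dict[str, str] = {}
    for i, (s, e) in enumerate(intervals):
        gid = f"orf{i:04d}"
        features.append(GeneFeature(gid, genome_id, s, e, str(strands[i]), rank=i))
        mid = (s + e) // 2
        terminal = mid <= window or mid > length - window
        p = p_cat_terminal if terminal else p_cat_central
        positive = bool(rng.random() < p)
        category[gid] = CATEGORY_POSITIVE if positive else CATEGORY_NEGATIVE
    genome = Genome(genome_id, length, tuple(features))
    return genome, GenomeTruth(category_of=category)


# ---------------------------------------------------------------------------
# hit tables consistent with planted orthology
# ---------------------------------------------------------------------------


def _mk_hit(
    rng: np.random.Generator, q: str, s: str, evalue: float
) -> HitRecord:
    logscore = max(0.0, -math.log10(max(evalue, 1e-180)))
    aln = int(rng.integers(80, 401))
    pid = float(np.round(rng.uniform(22.0, 85.0), 1))
    return HitRecord(
        query_id=q,
        subject_id=s,
        pct_identity=pid,
        aln_length=aln,
        mismatches=int(aln * (100.0 - pid) / 100.0),
        gap_opens=int(rng.integers(0, 4)),
        q_start=1,
        q_end=aln,
        s_start=1,
        s_end=aln,
        evalue=float(evalue),
        bitscore=float(np.round(30.0 + 2.0 * logscore + rng.uniform(0, 5), 1)),
    )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def gen_hit_table(
    planted_pairs: Iterable[tuple[str, str]],
    decoy_ids: tuple[Iterable[str], Iterable[str]],
    fp_rate: float,
    fn_rate: float,
    seed: int,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Mutual hit tables (A→B, B→A) consistent with a planted ortholog pairing.

    Each planted pair emits mutual hits with e-values log-uniform on
    [1e-150, 1e-20] unless the pair is dropped with probability ``fn_rate``.
    Every decoy emits a background hit at an insignificant e-value
    (uniform in log space on [1e-4, 1]) toward a random partner, and, with
    probability ``fp_rate``, an additional *mutual* spurious hit at a
    significant e-value (log-uniform on [1e-30, 1e-6]) — the spurious hits are
    reciprocal so that false RBH pairs can actually arise.
    """
    for name, r in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = sorted(planted_pairs)
    decoys_a = sorted(map(str, decoy_ids[0]))
    decoys_b = sorted(map(str, decoy_ids[1]))
    a_ids = sorted({a for a, _ in pairs} | set(decoys_a))
    b_ids = sorted({b for _, b in pairs} | set(decoys_b))
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    for a, b in pairs:
        if rng.random() < fn_rate:
            continue
        e_ab = _log_uniform(rng, 1e-150, 1e-20)
        e_ba = _log_uniform(rng, 1e-150, 1e-20)
        hits_ab.append(_mk_hit(rng, a, b, e_ab))
        hits_ba.append(_mk_hit(rng, b, a, e_ba))

    def decoy_hits(ids: Sequence[str], partners: Sequence[str], out_fwd, out_rev):
        for d in ids:
            if not partners:
                break
            partner = partners[int(rng.integers(0, len(partners)))]
            out_fwd.append(_mk_hit(rng, d, partner, _log_uniform(rng, 1e-4, 1.0)))
            if rng.random() < fp_rate:
                e = _log_uniform(rng, 1e-30, 1e-6)
                spur = partners[int(rng.integers(0, len(partners)))]
                out_fwd.append(_mk_hit(rng, d, spur, e))
                out_rev.append(_mk_hit(rng, spur, d, e))

    decoy_hits(decoys_a, b_ids, hits_ab, hits_ba)
    decoy_hits(decoys_b, a_ids, hits_ba, hits_ab)
    return hits_ab, hits_ba


# ---------------------------------------------------------------------------
# coding sequences with specified codon weights
# ---------------------------------------------------------------------------


def gen_coding_sequences(
    n_genes: int,
    codon_weights: Mapping[str, float] | None,
    gene_length_codons: int,
    seed: int,
) -> list[SeqRecord]:
    """Coding sequences whose codons are drawn i.i.d. with the given weights.

    Unspecified sense codons default to weight 1 (uniform within every
    synonymous family); stop codons may not carry weight.  Each record has
    length ``3 * gene_length_codons``.
    """
    if gene_length_codons < 1:
        raise ValueError("gene_length_codons must be >= 1")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    weights = {c: 1.0 for c in SENSE_CODONS}
    if codon_weights:
        for codon, w in codon_weights.items():
            codon = codon.upper().replace("U", "T")
            if codon in STOP_CODONS:
                raise ValueError(f"weight on stop codon {codon!r}")
            if codon not in weights:
                raise ValueError(f"unknown codon {codon!r}")
            if w < 0:
                raise ValueError(f"negative weight for codon {codon!r}")
            weights[codon] = float(w)
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("at least one codon weight must be positive")
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    probs = np.array([weights[c] for c in SENSE_CODONS]) / total
    records = []
    for i in range(n_genes):
        draw = rng.choice(codons, size=gene_length_codons, p=probs)
        records.append(make_seq_record("".join(draw), f"gene{i + 1:04d}"))
    return records
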