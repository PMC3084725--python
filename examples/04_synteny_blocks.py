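"""Find conserved gene-order blocks (synteny) between two genomes.

Builds two 20-gene genomes whose orthologs are mostly shuffled but share one
collinear run of 4 genes and one inverted run of 3, then detects the blocks.
"""

from nclvkit.homology import OrthologPair
from nclvkit.io_formats import GeneFeature, Genome
from nclvkit.synteny import synteny_blocks


def genome(prefix, n):
    feats = [GeneFeature(f"{prefix}{i}", prefix, 1 + 1000 * i, 800 + 1000 * i, "+", 0)
             for i in range(n)]
    return Genome.from_features(prefix, 1000 * n + 1000, feats)


ga, gb = genome("a", 20), genome("b", 20)

# b-ranks per a-rank: collinear run at a-ranks 2..5, inverted run at 10..12
rank_b = [15, 7, 0, 1, 2, 3, 18, 9, 16, 5, 12, 11, 10, 19, 4, 8, 17, 13, 6, 14]
pairs = {OrthologPair(f"a{i}", f"b{rank_b[i]}", 1e-120, 1e-115, 400.0)
         for i in range(20)}

for blk in synteny_blocks(pairs, ga, gb, e_max=1e-100, gap=0):
    genes = " ".join(f"{x}~{y}" for x, y in blk.genes)
    print(f"{blk.orientation:9s} block of {len(blk)}: {genes}")
# Runs of >=2 consecutive orthologs in consistent order are reported; all
# other (shuffled) pairs stay outside any block.
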