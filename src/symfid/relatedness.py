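"""Genome relatedness: fragment-based ANI and a 1-100 collinearity score.

Two complementary distances between a pair of reduced symbiont genomes:

* **ANI** (average nucleotide identity): genome A is cut into consecutive
  non-overlapping fragments (default 1,020 bp, the ANIb convention); each
  fragment is placed in genome B by exact 15-mer seeding followed by gapped
  alignment of the seeded window (edlib), on both strands; fragments passing
  identity/coverage retention thresholds contribute their percent identity
  to the mean.

* **Collinearity score**: reciprocal-best ortholog pairs (global gene
  alignment, identity >= 70%, coverage >= 70%) are chained into collinear
  blocks (maximal runs monotone in both genomes' gene order, forward or
  inverted, tolerating small positional gaps).  The smaller genome is then
  scanned in fixed windows of consecutive genes ("comparable regions"); a
  window's pairwise synteny score is the fraction of its ortholog gene
  pairs that co-occur in a single collinear block.  The average pairwise
  synteny score (APSS) times the number of comparable regions, normalised
  by the smaller genome's length, gives a raw score that is anchored so a
  self-comparison scores 100 and absence of homology scores 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .synthetic import reverse_complement


class NoHomologyError(ValueError):
    """No fragment survived retention: the genomes share no detectable homology."""


# ---------------------------------------------------------------------------
# ANI


@dataclass(frozen=True)
class AniParams:
    fragment_len: int = 1020
    min_fragment_identity: float = 0.30
    min_fragment_coverage: float = 0.70
    seed_k: int = 15

    def __post_init__(self):
        if self.fragment_len < 100:
            raise ValueError("fragment_len must be >= 100")
        for f in (self.min_fragment_identity, self.min_fragment_coverage):
            if not 0.0 <= f <= 1.0:
                raise ValueError("retention thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class AniResult:
    ani_percent: float
    aligned_fraction: float
    n_fragments: int = 0


def _kmer_index(seq: str, k: int, max_hits: int = 50) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    # drop highly repetitive seeds
    return {kmer: pos for kmer, pos in index.items() if len(pos) <= max_hits}


def _best_fragment_identity(
    frag: str, target: str, index: dict[str, list[int]], k: int, pad: int = 40
) -> tuple[float, float] | None:
    """(identity, coverage) of the best seeded placement, or None if unseeded."""
    votes: Counter[int] = Counter()
    for i in range(len(frag) - k + 1):
        for pos in index.get(frag[i : i + k], ()):
            votes[pos - i] += 1
    if not votes:
        return None
    best = None
    for diag, _ in votes.most_common(2):
        start = max(diag - pad, 0)
        end = min(diag + len(frag) + pad, len(target))
        window = target[start:end]
        if not window:
            continue
        dist = edlib.align(frag, window, mode="HW", task="distance")["editDistance"]
        identity = 1.0 - dist / len(frag)
        coverage = min(1.0, len(window) / len(frag))
        if best is None or identity > best[0]:
            best = (identity, coverage)
    return best


def compute_ani(genome_a: str, genome_b: str, params: AniParams = AniParams()) -> AniResult:
    """Fragment-based average nucleotide identity of A against B, in percent.

    Raises :class:`NoHomologyError` when no fragment is retained, which is
    distinct from a (never produced) ANI of zero.
    """
    if not genome_a or not genome_b:
        raise ValueError("genomes must be non-empty")
    k = params.seed_k
    index = _kmer_index(genome_b, k)
    identities = []
    n_frag = 0
    for start in range(0, len(genome_a) - params.fragment_len + 1, params.fragment_len):
        frag = genome_a[start : start + params.fragment_len]
        n_frag += 1
        hits = [
            _best_fragment_identity(frag, genome_b, index, k),
            _best_fragment_identity(reverse_complement(frag), genome_b, index, k),
        ]
        hits = [h for h in hits if h is not None]
        if not hits:
            continue
        identity, coverage = max(hits)
        if identity >= params.min_fragment_identity and coverage >= params.min_fragment_coverage:
            identities.append(identity)
    if n_frag == 0:
        raise ValueError(f"genome A shorter than one fragment ({params.fragment_len} bp)")
    if not identities:
        raise NoHomologyError("no homology detected between the two genomes")
    return AniResult(
        ani_percent=100.0 * float(np.mean(identities)),
        aligned_fraction=len(identities) / n_frag,
        n_fragments=n_frag,
    )


# ---------------------------------------------------------------------------
# orthologs and collinear blocks


@dataclass(frozen=True)
class Gene:
    gene_id: str
    ordinal: int  # 0-based rank along the genome
    strand: str
    seq: str  # oriented 5'->3' on the coding strand


@dataclass(frozen=True)
class OrthologPair:
    gene_id_a: str
    gene_id_b: str
    pos_a: int
    pos_b: int
    strand_agreement: bool
    identity: float


def extract_genes(genome: str, coords: pd.DataFrame) -> list[Gene]:
    """Gene list from 1-based inclusive coordinates (gene_id, start, end, strand)."""
    genes = []
    ordered = coords.sort_values("start").reset_index(drop=True)
    for ordinal, row in ordered.iterrows():
        seq = genome[int(row.start) - 1 : int(row.end)]
        if row.strand == "-":
            seq = reverse_complement(seq)
        genes.append(Gene(str(row.gene_id), int(ordinal), str(row.strand), seq))
    return genes


def _gene_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) from a global alignment of two gene sequences."""
    la, lb = len(a), len(b)
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    longer = max(la, lb)
    return 1.0 - dist / longer, min(la, lb) / longer


def find_ortholog_pairs(
    genes_a: list[Gene],
    genes_b: list[Gene],
    min_identity: float = 0.70,
    min_coverage: float = 0.70,
) -> list[OrthologPair]:
    """Reciprocal-best gene pairs above identity and coverage thresholds."""
    if not genes_a or not genes_b:
        raise ValueError("empty gene set")
    ident = np.zeros((len(genes_a), len(genes_b)))
    cover = np.zeros_like(ident)
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            ident[i, j], cover[i, j] = _gene_identity(ga.seq, gb.seq)
    best_for_a = ident.argmax(axis=1)
    best_for_b = ident.argmax(axis=0)
    pairs = []
    for i, j in enumerate(best_for_a):
        if (
            best_for_b[j] == i
            and ident[i, j] >= min_identity
            and cover[i, j] >= min_coverage
        ):
            ga, gb = genes_a[i], genes_b[int(j)]
            pairs.append(
                OrthologPair(
                    gene_id_a=ga.gene_id,
                    gene_id_b=gb.gene_id,
                    pos_a=ga.ordinal,
                    pos_b=gb.ordinal,
                    strand_agreement=(ga.strand == gb.strand),
                    identity=float(ident[i, j]),
                )
            )
    return pairs


@dataclass
class CollinearBlock:
    pairs: list[OrthologPair]
    orientation: int  # +1 forward, -1 inverted

    def __len__(self):
        return len(self.pairs)


def chain_collinear_blocks(
    pairs: list[OrthologPair], min_block_size: int = 3, max_gap: int = 5
) -> list[CollinearBlock]:
    """Chain ortholog pairs into maximal collinear runs.

    Pairs are scanned in genome-A gene order; a run extends while the B-side
    ordinal moves monotonically in the run's direction (forward runs require
    strand agreement, inverted runs require disagreement) and neither
    genome's positional gap exceeds ``max_gap`` genes.  Runs shorter than
    ``min_block_size`` are discarded; the sequential scan assigns each pair
    to at most one block.
    """
    ordered = sorted(pairs, key=lambda p: p.pos_a)
    blocks: list[CollinearBlock] = []
    run: list[OrthologPair] = []
    orient = 0

    def close():
        nonlocal run, orient
        if len(run) >= min_block_size:
            blocks.append(CollinearBlock(pairs=run, orientation=orient))
        run, orient = [], 0

    for p in ordered:
        p_orient = 1 if p.strand_agreement else -1
        if run:
            prev = run[-1]
            da = p.pos_a - prev.pos_a
            db = (p.pos_b - prev.pos_b) * orient
            if p_orient == orient and 1 <= da <= max_gap + 1 and 1 <= db <= max_gap + 1:
                run.append(p)
                continue
            close()
        run = [p]
        orient = p_orient
    close()
    return blocks


# ---------------------------------------------------------------------------
# collinearity score


@dataclass(frozen=True)
class CollinearityParams:
    min_identity: float = 0.70
    min_coverage: float = 0.70
    min_block_size: int = 3
    max_gap: int = 5
    window_genes: int = 5  # genes per comparable region of the smaller genome


@dataclass(frozen=True)
class CollinearityResult:
    apss: float
    n_regions: int
    smaller_genome_len: int
    raw_score: float
    score_1_100: float


def _window_scores(
    n_genes_small: int,
    pairs: list[OrthologPair],
    blocks: list[CollinearBlock],
    window_genes: int,
    small_is_a: bool,
) -> list[float]:
    """Per-window pairwise synteny scores over the smaller genome's genes.

    Windows slide with stride 1 so every rearrangement breakpoint is
    straddled by some window whatever its phase.  A window is comparable
    when it holds at least two ortholog-bearing genes; its score is the
    fraction of those gene pairs falling in one and the same collinear
    block.
    """
    block_of: dict[int, int] = {}
    for b_idx, block in enumerate(blocks):
        for p in block.pairs:
            block_of[p.pos_a if small_is_a else p.pos_b] = b_idx
    pos_with_ortholog = sorted(p.pos_a if small_is_a else p.pos_b for p in pairs)
    scores = []
    for w_start in range(0, n_genes_small - window_genes + 1):
        members = [p for p in pos_with_ortholog if w_start <= p < w_start + window_genes]
        m = len(members)
        if m < 2:
            continue
        same = 0
        for i in range(m):
            for j in range(i + 1, m):
                bi = block_of.get(members[i])
                if bi is not None and bi == block_of.get(members[j]):
                    same += 1
        scores.append(same / (m * (m - 1) / 2))
    return scores


def _raw_score(
    genome_a: str,
    genome_b: str,
    coords_a: pd.DataFrame,
    coords_b: pd.DataFrame,
    params: CollinearityParams,
) -> tuple[float, int, float]:
    """(apss, n_regions, raw_score) for one genome pair."""
    genes_a = extract_genes(genome_a, coords_a)
    genes_b = extract_genes(genome_b, coords_b)
    pairs = find_ortholog_pairs(
        genes_a, genes_b, params.min_identity, params.min_coverage
    )
    small_is_a = len(genome_a) <= len(genome_b)
    n_small_genes = len(genes_a) if small_is_a else len(genes_b)
    smaller_len = min(len(genome_a), len(genome_b))
    if not pairs:
        return 0.0, 0, 0.0
    blocks = chain_collinear_blocks(pairs, params.min_block_size, params.max_gap)
    scores = _window_scores(n_small_genes, pairs, blocks, params.window_genes, small_is_a)
    if not scores:
        return 0.0, 0, 0.0
    apss = float(np.mean(scores))
    n_regions = len(scores)
    return apss, n_regions, apss * n_regions / smaller_len


def collinearity_score(
    genome_a: str,
    genome_b: str,
    coords_a: pd.DataFrame,
    coords_b: pd.DataFrame,
    params: CollinearityParams = CollinearityParams(),
) -> CollinearityResult:
    """1-100 collinearity score between two annotated genomes.

    The raw score (APSS x number of comparable regions / smaller genome
    length) is rescaled against the smaller genome's self-comparison:
    score = 1 + 99 * min(1, raw / raw_self), so identity maps to 100 and no
    detectable homology to the floor of 1.
    """
    apss, n_regions, raw = _raw_score(genome_a, genome_b, coords_a, coords_b, params)
    if len(genome_a) <= len(genome_b):
        sg, sc = genome_a, coords_a
    else:
        sg, sc = genome_b, coords_b
    _, _, raw_self = _raw_score(sg, sg, sc, sc, params)
    smaller_len = min(len(genome_a), len(genome_b))
    if raw_self <= 0:
        score = 1.0
    else:
        score = 1.0 + 99.0 * min(1.0, raw / raw_self)
    return CollinearityResult(
        apss=apss,
        n_regions=n_regions,
        smaller_genome_len=smaller_len,
        raw_score=raw,
        score_1_100=score,
    )
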