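"""Pairwise ortholog inference and synteny-run decomposition.

Orthologs are bidirectional best hits (BBH) under Smith-Waterman local
alignment with BLOSUM62, admitted at >=30% identity over >=80% of the
shorter protein.  Synteny runs are maximal colinear chains of BBH pairs
tolerating up to ``max_gap`` intervening genes on each genome; whole-run
inversions are allowed.

A weighted longest-increasing-subsequence over the runs of a genome pair
defines the *backbone*: the dominant colinear order.  Runs off the backbone
are displaced (relocated blocks); genes whose pairs sit only in displaced
runs break synteny with respect to the reference context even though the
sequence is still present somewhere in the partner genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError
from .genome_io import GenomeRecord
from .params import ParameterSet

__all__ = [
    "OrthologPair",
    "OrthologTable",
    "SyntenyRun",
    "align_protein_pair",
    "build_ortholog_table",
    "find_synteny_runs",
    "backbone_run_ids",
    "syntenic_gene_ids",
    "ParameterSet",
]

OPEN_GAP = -11.0
EXTEND_GAP = -1.0


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = OPEN_GAP
    al.extend_gap_score = EXTEND_GAP
    al.mode = "local"
    return al


def align_protein_pair(a: str, b: str) -> tuple[float, float]:
    """Local-align two proteins; return (percent identity, coverage).

    Identity is measured over the aligned columns (gaps included) of the
    best local alignment; coverage is the aligned span on the shorter
    protein divided by its length.
    """
    if not a or not b:
        raise InputError("cannot align an empty protein sequence")
    al = _aligner()
    try:
        aln = al.align(a, b)[0]
    except IndexError:  # no positive-scoring local alignment at all
        return 0.0, 0.0
    counts = aln.counts()
    ncols = counts.gaps + counts.identities + counts.mismatches
    if ncols == 0:
        return 0.0, 0.0
    identity = 100.0 * counts.identities / ncols
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    span_short = span_a if len(a) <= len(b) else span_b
    coverage = span_short / min(len(a), len(b))
    return identity, coverage


@dataclass(frozen=True)
class OrthologPair:
    """One admitted ortholog relation between two genes."""

    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    bidirectional_best: bool
    rank_a: int
    rank_b: int
    replicon_a: str
    replicon_b: str


@dataclass
class OrthologTable:
    """Admitted ortholog pairs between one ordered genome pair."""

    genome_a: str
    genome_b: str
    pairs: list[OrthologPair]

    def __post_init__(self) -> None:
        self._bbh_by_a: dict[str, OrthologPair] = {}
        self._bbh_by_b: dict[str, OrthologPair] = {}
        self._by_a: dict[str, list[OrthologPair]] = {}
        for p in self.pairs:
            self._by_a.setdefault(p.gene_a, []).append(p)
            if p.bidirectional_best:
                self._bbh_by_a[p.gene_a] = p
                self._bbh_by_b[p.gene_b] = p

    @property
    def bbh_pairs(self) -> list[OrthologPair]:
        return [p for p in self.pairs if p.bidirectional_best]

    def bbh_partner(self, gene_a: str) -> OrthologPair | None:
        return self._bbh_by_a.get(gene_a)

    def has_ortholog(self, gene_a: str) -> bool:
        """Any admitted pair (not necessarily BBH) for a reference gene."""
        return gene_a in self._by_a

    def swapped(self) -> "OrthologTable":
        """The same relation with genome roles exchanged."""
        return OrthologTable(
            genome_a=self.genome_b,
            genome_b=self.genome_a,
            pairs=[
                OrthologPair(
                    gene_a=p.gene_b,
                    gene_b=p.gene_a,
                    identity=p.identity,
                    coverage=p.coverage,
                    bidirectional_best=p.bidirectional_best,
                    rank_a=p.rank_b,
                    rank_b=p.rank_a,
                    replicon_a=p.replicon_b,
                    replicon_b=p.replicon_a,
                )
                for p in self.pairs
            ],
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "identity": round(p.identity, 2),
                    "coverage": round(p.coverage, 4),
                    "bbh": int(p.bidirectional_best),
                }
                for p in self.pairs
            ],
            columns=["gene_a", "gene_b", "identity", "coverage", "bbh"],
        )


def _candidate_hits(prot_a, prot_b, top_k: int = 3):
    """Score all-vs-all cheaply, keep each gene's top-k partners."""
    al = _aligner()
    scores: dict[tuple[int, int], float] = {}
    for i, ga in enumerate(prot_a):
        for j, gb in enumerate(prot_b):
            s = al.score(ga.protein, gb.protein)
            if s > 0:
                scores[(i, j)] = s
    cand: set[tuple[int, int]] = set()
    best_a: dict[int, list[tuple[float, str, int]]] = {}
    best_b: dict[int, list[tuple[float, str, int]]] = {}
    for (i, j), s in scores.items():
        best_a.setdefault(i, []).append((-s, prot_b[j].feature_id, j))
        best_b.setdefault(j, []).append((-s, prot_a[i].feature_id, i))
    for i, hits in best_a.items():
        for _, _, j in sorted(hits)[:top_k]:
            cand.add((i, j))
    for j, hits in best_b.items():
        for _, _, i in sorted(hits)[:top_k]:
            cand.add((i, j))
    return cand


def build_ortholog_table(
    A: GenomeRecord,
    B: GenomeRecord,
    params: ParameterSet | None = None,
    include_plasmids: bool = False,
) -> OrthologTable:
    """All-vs-all protein comparison filtered at the identity/coverage
    thresholds, with bidirectional best hits flagged.

    Best hits are ranked by (identity, coverage, lexicographic partner id);
    a gene enters at most one BBH pair per partner genome.  A genome with
    zero eligible CDS yields an empty table (warning condition, not an
    error).
    """
    params = params or ParameterSet()
    prot_a = A.proteome(include_plasmids=include_plasmids)
    prot_b = B.proteome(include_plasmids=include_plasmids)
    if not prot_a or not prot_b:
        return OrthologTable(A.genome_id, B.genome_id, [])
    cand = _candidate_hits(prot_a, prot_b)
    admitted: dict[tuple[int, int], tuple[float, float]] = {}
    for i, j in sorted(cand):
        ident, cov = align_protein_pair(prot_a[i].protein, prot_b[j].protein)
        if ident >= params.min_identity and cov >= params.min_coverage:
            admitted[(i, j)] = (ident, cov)

    def _best(hits: list[tuple[float, float, str, int]]) -> int:
        # highest identity, then highest coverage, then lexicographic id
        hits.sort(key=lambda h: (-h[0], -h[1], h[2]))
        return hits[0][3]

    by_a: dict[int, list[tuple[float, float, str, int]]] = {}
    by_b: dict[int, list[tuple[float, float, str, int]]] = {}
    for (i, j), (ident, cov) in admitted.items():
        by_a.setdefault(i, []).append((ident, cov, prot_b[j].feature_id, j))
        by_b.setdefault(j, []).append((ident, cov, prot_a[i].feature_id, i))
    best_of_a = {i: _best(hits) for i, hits in by_a.items()}
    best_of_b = {j: _best(hits) for j, hits in by_b.items()}
    pairs: list[OrthologPair] = []
    for (i, j), (ident, cov) in sorted(admitted.items()):
        ga, gb = prot_a[i], prot_b[j]
        bbh = best_of_a.get(i) == j and best_of_b.get(j) == i
        pairs.append(
            OrthologPair(
                gene_a=ga.feature_id,
                gene_b=gb.feature_id,
                identity=ident,
                coverage=cov,
                bidirectional_best=bbh,
                rank_a=ga.rank,
                rank_b=gb.rank,
                replicon_a=ga.replicon_id,
                replicon_b=gb.replicon_id,
            )
        )
    return OrthologTable(A.genome_id, B.genome_id, pairs)


@dataclass
class SyntenyRun:
    """A maximal colinear chain of BBH pairs (colocalized orthologs)."""

    run_id: str
    pairs: list[OrthologPair]  # ordered by rank_a
    direction: int  # +1 colinear, -1 inverted, 0 singleton
    replicon_a: str
    replicon_b: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def span_a(self) -> tuple[int, int]:
        return self.pairs[0].rank_a, self.pairs[-1].rank_a

    @property
    def median_rank_b(self) -> float:
        ranks = sorted(p.rank_b for p in self.pairs)
        return ranks[len(ranks) // 2]


def _chainable(p: OrthologPair, q: OrthologPair, direction: int, max_gap: int):
    """Whether q can extend a run ending at p; returns the new direction."""
    da = q.rank_a - p.rank_a
    if not 0 < da <= max_gap + 1:
        return None
    db = q.rank_b - p.rank_b
    if db == 0:
        return None
    d = 1 if db > 0 else -1
    if direction and d != direction:
        return None
    if not abs(db) <= max_gap + 1:
        return None
    return d


def find_synteny_runs(
    table: OrthologTable,
    params: ParameterSet | None = None,
    circular_a: set[str] | None = None,
    circular_b: set[str] | None = None,
) -> list[SyntenyRun]:
    """Decompose the BBH pairs of a genome pair into maximal colinear runs.

    Pairs are chained left to right along the reference; gaps of up to
    ``max_gap`` genes are tolerated on both genomes; partner ranks must be
    monotone within a run (either direction).  Singleton runs are permitted.
    When both replicons are circular, the first and last run of a replicon
    pair are merged if they chain across the origin.
    """
    params = params or ParameterSet()
    circular_a = circular_a or set()
    circular_b = circular_b or set()
    groups: dict[tuple[str, str], list[OrthologPair]] = {}
    for p in table.bbh_pairs:
        groups.setdefault((p.replicon_a, p.replicon_b), []).append(p)
    runs: list[SyntenyRun] = []
    for (rep_a, rep_b), pairs in sorted(groups.items()):
        pairs.sort(key=lambda p: p.rank_a)
        chains: list[tuple[list[OrthologPair], int]] = []
        cur: list[OrthologPair] = [pairs[0]]
        direction = 0
        for q in pairs[1:]:
            d = _chainable(cur[-1], q, direction, params.max_gap)
            if d is None:
                chains.append((cur, direction))
                cur, direction = [q], 0
            else:
                cur.append(q)
                direction = d
        chains.append((cur, direction))
        # origin wrap: merge last chain into first when both replicons are
        # circular and the chain relation holds across the origin
        if (
            len(chains) > 1
            and rep_a in circular_a
            and rep_b in circular_b
        ):
            n_a = max(p.rank_a for p in pairs) + 1
            last_pairs, last_dir = chains[-1]
            first_pairs, first_dir = chains[0]
            p_end, q_start = last_pairs[-1], first_pairs[0]
            da = (q_start.rank_a - p_end.rank_a) % n_a
            db = q_start.rank_b - p_end.rank_b
            d = 1 if db > 0 else (-1 if db < 0 else 0)
            dirs_ok = (
                d != 0
                and (last_dir in (0, d))
                and (first_dir in (0, d))
            )
            if 0 < da <= params.max_gap + 1 and dirs_ok and abs(db) <= params.max_gap + 1:
                chains[0] = (last_pairs + first_pairs, d)
                chains.pop()
        for chain, direction in chains:
            runs.append(
                SyntenyRun(
                    run_id="",
                    pairs=chain,
                    direction=direction,
                    replicon_a=rep_a,
                    replicon_b=rep_b,
                )
            )
    runs.sort(key=lambda r: (r.replicon_a, r.pairs[0].rank_a, r.replicon_b))
    for i, r in enumerate(runs):
        r.run_id = f"{table.genome_b}:r{i}"
    return runs


def backbone_run_ids(runs: list[SyntenyRun]) -> set[str]:
    """Run ids on the dominant colinear backbone of a genome pair.

    Per reference replicon, runs of the dominant partner replicon (largest
    total pair count) are chained by a weighted longest monotone
    subsequence over their partner positions; the heavier of the increasing
    and decreasing solutions is the backbone.  Runs left out are displaced
    (translocated or inverted out of order).
    """
    by_rep_a: dict[str, list[SyntenyRun]] = {}
    for r in runs:
        by_rep_a.setdefault(r.replicon_a, []).append(r)
    backbone: set[str] = set()
    for rep_runs in by_rep_a.values():
        weight_by_b: dict[str, int] = {}
        for r in rep_runs:
            weight_by_b[r.replicon_b] = weight_by_b.get(r.replicon_b, 0) + r.n_pairs
        dominant_b = max(sorted(weight_by_b), key=lambda k: weight_by_b[k])
        cand = [r for r in rep_runs if r.replicon_b == dominant_b]
        cand.sort(key=lambda r: r.pairs[0].rank_a)
        vals = [r.median_rank_b for r in cand]
        wts = [r.n_pairs for r in cand]
        best_ids: set[str] = set()
        best_weight = -1
        for sign in (1, -1):
            v = [sign * x for x in vals]
            n = len(v)
            dp = list(wts)
            prev = [-1] * n
            for i in range(n):
                for j in range(i):
                    if v[j] < v[i] and dp[j] + wts[i] > dp[i]:
                        dp[i] = dp[j] + wts[i]
                        prev[i] = j
            if not n:
                continue
            i = max(range(n), key=lambda k: (dp[k], -k))
            if dp[i] > best_weight:
                best_weight = dp[i]
                ids = set()
                while i != -1:
                    ids.add(cand[i].run_id)
                    i = prev[i]
                best_ids = ids
        backbone |= best_ids
    return backbone


def syntenic_gene_ids(
    runs: list[SyntenyRun],
    backbone_only: bool = True,
    min_run_pairs: int = 2,
) -> set[str]:
    """Reference gene ids with a syntenic (colocalized) ortholog.

    A gene qualifies when its BBH pair sits in a run of at least
    ``min_run_pairs`` pairs; with ``backbone_only`` the run must also lie on
    the dominant colinear backbone (in-place conservation, the notion used
    for synteny-break detection).  Without it, conservation anywhere counts
    (the notion used for module conservation).
    """
    keep = backbone_run_ids(runs) if backbone_only else None
    out: set[str] = set()
    for r in runs:
        if r.n_pairs < min_run_pairs:
            continue
        if keep is not None and r.run_id not in keep:
            continue
        out.update(p.gene_a for p in r.pairs)
    return out
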