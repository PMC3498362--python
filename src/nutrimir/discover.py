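"""Novel miRNA discovery from unannotated mapped tags.

Candidate loci are built by single-linkage clustering of "other"-class tags
(excluding anything matching a known mature miRNA), two flanking windows per
cluster are excised from the genome so the mature can sit near either hairpin
arm, each window is folded, and standard hairpin annotation criteria are
applied: the mature must lie in one arm of the stem-loop (all its pairing
partners across the terminal loop), with at most ``max_unpaired_mature``
unpaired mature bases and no internal unpaired run (bulge/loop) longer than
``max_bulge``. The star sequence is derived from the duplex geometry (2-nt 3'
overhangs on both ends) and its presence in the sequencing data is reported,
not required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .fold import FoldEngine, fold_rna, pair_table
from .io import GenomeLocus
from .mapper import MappedTag
from .preprocess import ReadTagTable

DEFAULT_MERGE_DISTANCE = 30
DEFAULT_MIN_COUNT = 5
DEFAULT_MAX_NLOCI = 5
DEFAULT_LONG_FLANK = 150
DEFAULT_SHORT_FLANK = 20
DEFAULT_MAX_UNPAIRED_MATURE = 4
DEFAULT_MAX_BULGE = 2
MATURE_LENGTHS = (20, 24)


@dataclass
class LocusCluster:
    locus: GenomeLocus  # merged span
    representative: str  # highest-count tag sequence (ties: lexicographic)
    rep_locus: GenomeLocus
    members: list[str]
    count_A: int
    count_B: int

    @property
    def combined_count(self) -> int:
        return self.count_A + self.count_B


@dataclass
class HairpinCandidate:
    precursor: str
    structure: str
    score: int
    mature_offset: int
    mature_len: int
    in_one_arm: bool = False
    unpaired_mature: int = 0
    max_bulge_run: int = 0
    outside_loop: bool = False
    coherent_pairs: int = 0
    star_interval: tuple[int, int] | None = None  # [start, end) in precursor
    star_sequence: str | None = None
    star_supported: bool = False
    star_read_count: int = 0
    flags: dict = field(default_factory=dict)
    window_span: tuple[int, int] | None = None  # genomic [start0, end) of the window

    @property
    def passes(self) -> bool:
        return bool(self.flags) and all(self.flags.values())


def cluster_loci(
    mapped: list[MappedTag],
    classes: dict[str, str],
    known_matures: set[str] | frozenset[str] = frozenset(),
    table: ReadTagTable | None = None,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    min_count: int = DEFAULT_MIN_COUNT,
    max_nloci: int = DEFAULT_MAX_NLOCI,
    mature_lengths: tuple[int, int] = MATURE_LENGTHS,
) -> list[LocusCluster]:
    """Single-linkage merge of qualifying tag loci per chromosome and strand."""
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    counts: dict[str, tuple[int, int]] = {}
    if table is not None:
        counts = {
            r.sequence: (int(r.count_A), int(r.count_B))
            for r in table.df.itertuples(index=False)
        }
    lo, hi = mature_lengths
    entries = []  # (chrom, strand, start, end, seq)
    for tag in mapped:
        if classes.get(tag.sequence) != "other":
            continue
        if tag.sequence in known_matures:
            continue
        if not (lo <= len(tag.sequence) <= hi):
            continue
        if tag.n_loci > max_nloci:
            continue
        a, b = counts.get(tag.sequence, (0, 0))
        if a + b < min_count:
            continue
        for loc in tag.loci:
            entries.append((loc.chrom, loc.strand, loc.start, loc.end, tag.sequence))
    entries.sort()

    clusters: list[LocusCluster] = []
    group: list[tuple] = []

    def flush(group: list[tuple]) -> None:
        if not group:
            return
        chrom, strand = group[0][0], group[0][1]
        start = min(g[2] for g in group)
        end = max(g[3] for g in group)
        seqs = sorted({g[4] for g in group})
        # representative: highest combined count, ties broken lexicographically
        rep = min(seqs, key=lambda s: (-(counts.get(s, (0, 0))[0] + counts.get(s, (0, 0))[1]), s))
        rep_entry = min(g for g in group if g[4] == rep)
        a = sum(counts.get(s, (0, 0))[0] for s in seqs)
        b = sum(counts.get(s, (0, 0))[1] for s in seqs)
        clusters.append(
            LocusCluster(
                locus=GenomeLocus(chrom, start, end, strand),
                representative=rep,
                rep_locus=GenomeLocus(chrom, rep_entry[2], rep_entry[3], strand),
                members=seqs,
                count_A=a,
                count_B=b,
            )
        )

    for e in entries:
        if group and (
            e[0] != group[-1][0]
            or e[1] != group[-1][1]
            or e[2] > max(g[3] for g in group) + merge_distance
        ):
            flush(group)
            group = []
        group.append(e)
    flush(group)
    return clusters


def extract_precursors(
    cluster: LocusCluster,
    chroms: dict[str, str],
    long_flank: int = DEFAULT_LONG_FLANK,
    short_flank: int = DEFAULT_SHORT_FLANK,
) -> list[tuple[str, int]]:
    """Two candidate precursor windows, each as (sequence 5'->3', mature offset).

    Windows span [start - long_flank, end + short_flank] and the mirror
    layout; minus-strand clusters are reverse-complemented so the mature reads
    5'->3' within the returned precursor. Windows are clipped at contig edges.
    """
    if long_flank <= 0 or short_flank <= 0:
        raise ValueError("flanks must be > 0")
    chrom_seq = chroms[cluster.rep_locus.chrom]
    s, e = cluster.rep_locus.start, cluster.rep_locus.end
    out = []
    for left, right in ((long_flank, short_flank), (short_flank, long_flank)):
        ws = max(0, s - left)
        we = min(len(chrom_seq), e + right)
        if we - ws <= (e - s):
            raise ValueError("window fully clipped at contig edge")
        window = chrom_seq[ws:we]
        if cluster.rep_locus.strand == "+":
            offset = s - ws
        else:
            window = revcomp(window)
            offset = we - e
        out.append((window, offset))
    return out


def best_duplex_diagonal(
    seq: str, m0: int, m1: int, min_gap: int = 3
) -> tuple[int, int]:
    """Best antiparallel ungapped duplex partner of seq[m0:m1] within seq.

    Returns (pairable count, antidiagonal D) maximizing the number of mature
    positions p whose opposite base seq[D - p] can pair (Watson-Crick or G:U),
    over diagonals whose partner window does not overlap the mature and leaves
    at least ``min_gap`` nt of loop. Ties break to the smaller loop, then
    smaller D.
    """
    from .fold import pair_weight

    n = len(seq)
    best_key = (-1, 0, 0)  # (count, -loop_gap, -D)
    for D in range(0, 2 * n - 1):
        lo, hi = D - (m1 - 1), D - m0  # partner window [lo, hi] inclusive
        if lo < 0 or hi >= n:
            continue
        if not (hi < m0 - min_gap or lo > (m1 - 1) + min_gap):
            continue
        count = sum(
            1 for p in range(m0, m1) if pair_weight(seq[p], seq[D - p]) > 0
        )
        gap = (m0 - hi) if hi < m0 else (lo - (m1 - 1))
        key = (count, -gap, -D)
        if key > best_key:
            best_key = key
    return best_key[0], -best_key[2]


def _anchored_helix(seq: str, m0: int, L: int, diag: int) -> tuple[str, int]:
    """Dot-bracket of the single mature:star helix on antidiagonal ``diag``.

    Pairs every pairable mature position p with seq[diag - p]; everything
    else stays unpaired. Returns (structure, summed pair weight).
    """
    from .fold import pair_weight

    structure = ["."] * len(seq)
    score = 0
    for p in range(m0, m0 + L):
        q = diag - p
        if 0 <= q < len(seq) and q != p:
            w = pair_weight(seq[p], seq[q])
            if w:
                structure[min(p, q)] = "("
                structure[max(p, q)] = ")"
                score += w
    return "".join(structure), score


def _longest_dot_run(structure: str, start: int, end: int) -> int:
    run = best = 0
    for c in structure[start:end]:
        run = run + 1 if c == "." else 0
        best = max(best, run)
    return best


def evaluate_hairpin(
    precursor: str,
    structure: str,
    mature_offset: int,
    mature_len: int,
    max_unpaired_mature: int = DEFAULT_MAX_UNPAIRED_MATURE,
    max_bulge: int = DEFAULT_MAX_BULGE,
    score: int = 0,
) -> HairpinCandidate:
    """Apply the hairpin annotation criteria to a folded precursor window."""
    m0, m1 = mature_offset, mature_offset + mature_len  # [m0, m1)
    if m0 < 0 or m1 > len(precursor):
        raise ValueError("mature offset outside precursor")
    if len(structure) != len(precursor):
        raise ValueError("structure/sequence length mismatch")
    partners = pair_table(structure)
    cand = HairpinCandidate(
        precursor=precursor, structure=structure, score=score,
        mature_offset=mature_offset, mature_len=mature_len,
    )

    mature_pos = range(m0, m1)
    paired = [p for p in mature_pos if p in partners]
    unpaired_mature = mature_len - len(paired)

    in_one_arm = bool(paired)
    if paired:
        part = [partners[p] for p in paired]
        # all partners strictly on one side of the mature, none inside it
        if any(m0 <= q < m1 for q in part):
            in_one_arm = False
        elif not (all(q >= m1 for q in part) or all(q < m0 for q in part)):
            in_one_arm = False

    # terminal loop of the stem hosting the mature: innermost pair nested
    # between the mature arm and its partner arm. The mature may dangle a few
    # unpaired bases into the loop (the unpaired/bulge limits police that) but
    # must not span across it into the partner arm.
    outside_loop = True
    if in_one_arm and paired:
        p = max(paired) if partners[min(paired)] > m0 else min(paired)
        lo, hi = sorted((p, partners[p]))
        inner = [(a, partners[a]) for a in partners
                 if lo <= a < partners[a] <= hi]
        a_in, b_in = max(inner, key=lambda x: x[0])
        loop_lo, loop_hi = a_in + 1, b_in  # [loop_lo, loop_hi) terminal loop
        if m0 < loop_lo and m1 > loop_hi:
            outside_loop = False

    bulge = _longest_dot_run(structure, m0, m1)

    # duplex coherence: a genuine mature:star duplex is a near-contiguous
    # antiparallel stem, so most mature partners sit on one antidiagonal
    # p + partner(p) (within +-max_bulge for small bulges). Scattered pairing
    # that a maximization fold produces on random sequence fails this.
    coherent_pairs = 0
    if paired:
        diags = [p + partners[p] for p in paired]
        coherent_pairs = max(
            sum(1 for d in diags if abs(d - D) <= max_bulge) for D in set(diags)
        )

    cand.in_one_arm = in_one_arm
    cand.unpaired_mature = unpaired_mature
    cand.max_bulge_run = bulge
    cand.outside_loop = outside_loop
    cand.coherent_pairs = coherent_pairs
    cand.flags = {
        "in_one_arm": in_one_arm,
        "unpaired_mature_ok": unpaired_mature <= max_unpaired_mature,
        "max_bulge_ok": bulge <= max_bulge,
        "outside_loop": outside_loop,
        "stem_coherent": coherent_pairs >= mature_len - max_unpaired_mature,
    }
    return cand


def _stem_diagonal(partners: dict[int, int], m0: int, m1: int) -> int:
    """Dominant antidiagonal p + partner(p) of the mature's duplex.

    On a contiguous antiparallel stem p + partner(p) is constant; taking the
    modal value makes the star geometry robust to a few stray pairs the
    maximization fold may add. Ties break to the smallest diagonal.
    """
    paired = [p for p in range(m0, m1) if p in partners]
    if not paired:
        raise ValueError("mature fully unpaired; star undefined")
    votes: dict[int, int] = {}
    for p in paired:
        d = p + partners[p]
        votes[d] = votes.get(d, 0) + 1
    return min(votes, key=lambda d: (-votes[d], d))


def find_star(
    candidate: HairpinCandidate,
    table: ReadTagTable | None = None,
) -> HairpinCandidate:
    """Derive the star interval (2-nt 3' overhangs on both duplex ends) and
    report whether the sequencing data contains the star sequence (+-1 nt at
    either end)."""
    partners = pair_table(candidate.structure)
    m0 = candidate.mature_offset
    m1 = m0 + candidate.mature_len  # exclusive
    diag = _stem_diagonal(partners, m0, m1)
    # partner(x) = diag - x along the stem; +2 gives each strand's 3' overhang
    q5 = diag - m0 + 2  # partner of the mature 5' end -> star 3' end
    q3 = diag - (m1 - 1) + 2  # partner of the mature 3' end -> star 5' end
    s0, s1 = min(q5, q3), max(q5, q3) + 1  # star [s0, s1)
    s0 = max(0, s0)
    s1 = min(len(candidate.precursor), s1)
    candidate.star_interval = (s0, s1)
    candidate.star_sequence = candidate.precursor[s0:s1]

    if table is not None:
        variants = set()
        for ds in (-1, 0, 1):
            for de in (-1, 0, 1):
                a, b = s0 + ds, s1 + de
                if 0 <= a < b <= len(candidate.precursor):
                    variants.add(candidate.precursor[a:b])
        hits = table.df[table.df["sequence"].isin(variants)]
        candidate.star_supported = not hits.empty
        candidate.star_read_count = int(
            (hits["count_A"] + hits["count_B"]).sum()
        )
    return candidate


def star_interval_from_mature(
    structure: str, mature_offset: int, mature_len: int
) -> tuple[int, int]:
    """Star interval [start, end) implied by a mature interval on a structure."""
    partners = pair_table(structure)
    m0, m1 = mature_offset, mature_offset + mature_len
    diag = _stem_diagonal(partners, m0, m1)
    q5, q3 = diag - m0 + 2, diag - (m1 - 1) + 2
    return min(q5, q3), max(q5, q3) + 1


def discover_candidates(
    mapped: list[MappedTag],
    classes: dict[str, str],
    table: ReadTagTable,
    chroms: dict[str, str],
    known_matures: set[str] | frozenset[str] = frozenset(),
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    min_count: int = DEFAULT_MIN_COUNT,
    max_nloci: int = DEFAULT_MAX_NLOCI,
    long_flank: int = DEFAULT_LONG_FLANK,
    short_flank: int = DEFAULT_SHORT_FLANK,
    max_unpaired_mature: int = DEFAULT_MAX_UNPAIRED_MATURE,
    max_bulge: int = DEFAULT_MAX_BULGE,
    fold_engine: FoldEngine | None = None,
) -> list[tuple[LocusCluster, HairpinCandidate]]:
    """Full discovery pass: cluster, excise, fold, apply criteria, find stars.

    When both windows of a cluster pass, the higher pairing score wins; ties
    go to the window with more paired bases in total (longer stem). Clusters
    near a locus of a known mature miRNA are dropped (they are fragments of an
    already-annotated hairpin, e.g. its star); and because a hairpin locus
    carries the mature's exact reverse complement on the opposite strand,
    candidates whose windows overlap on the same chromosome are deduplicated,
    preferring star-supported, then higher-scoring, then plus-strand ones.
    """
    engine = fold_engine or fold_rna
    clusters = cluster_loci(
        mapped, classes, known_matures, table,
        merge_distance, min_count, max_nloci,
    )
    # exclusion zones: all loci of tags identical to a known mature sequence
    known_zones: list[tuple[str, int, int]] = []
    for tag in mapped:
        if tag.sequence in known_matures:
            for loc in tag.loci:
                known_zones.append(
                    (loc.chrom, loc.start - merge_distance, loc.end + merge_distance)
                )
    clusters = [
        c for c in clusters
        if not any(
            chrom == c.locus.chrom and c.locus.start < z1 and z0 < c.locus.end
            for chrom, z0, z1 in known_zones
        )
    ]
    results = []
    for cluster in clusters:
        try:
            windows = extract_precursors(cluster, chroms, long_flank, short_flank)
        except ValueError:
            continue
        passing = []
        chrom_len = len(chroms[cluster.rep_locus.chrom])
        s, e = cluster.rep_locus.start, cluster.rep_locus.end
        spans = [
            (max(0, s - long_flank), min(chrom_len, e + short_flank)),
            (max(0, s - short_flank), min(chrom_len, e + long_flank)),
        ]
        L = len(cluster.representative)
        for (window, offset), span in zip(windows, spans):
            structure, score = engine(window)
            cand = evaluate_hairpin(
                window, structure, offset, L,
                max_unpaired_mature, max_bulge, score=int(score),
            )
            cand.window_span = span
            if cand.passes:
                passing.append(cand)

        # duplex-anchored fallback: the global fold of a long window can bury
        # a perfect mature:star duplex in diffuse pairing. When neither
        # window passes, locate the best complementary arm of the mature in a
        # symmetric long-flank neighbourhood and evaluate that explicit
        # stem-loop helix (miRDeep-style duplex evaluation).
        if not passing:
            chrom_seq = chroms[cluster.rep_locus.chrom]
            us, ue = max(0, s - long_flank), min(chrom_len, e + long_flank)
            union = chrom_seq[us:ue]
            if cluster.rep_locus.strand == "+":
                rna, m0u = union, s - us
            else:
                rna, m0u = revcomp(union), ue - e
            n_pairable, diag = best_duplex_diagonal(rna, m0u, m0u + L)
            if n_pairable >= L - max_unpaired_mature:
                qlo, qhi = diag - (m0u + L - 1), diag - m0u  # partner window
                pad = 10
                a0 = max(0, min(m0u, qlo) - pad)
                a1 = min(len(rna), max(m0u + L, qhi + 1) + pad)
                sub = rna[a0:a1]
                structure, score = _anchored_helix(sub, m0u - a0, L, diag - 2 * a0)
                cand = evaluate_hairpin(
                    sub, structure, m0u - a0, L,
                    max_unpaired_mature, max_bulge, score=score,
                )
                if cluster.rep_locus.strand == "+":
                    cand.window_span = (us + a0, us + a1)
                else:
                    cand.window_span = (ue - a1, ue - a0)
                if cand.passes:
                    passing.append(cand)
        if not passing:
            continue
        best = max(
            passing, key=lambda c: (c.score, sum(ch != "." for ch in c.structure))
        )
        best = find_star(best, table)
        results.append((cluster, best))

    # strand/arm deduplication by overlapping window spans
    results.sort(key=lambda rc: (rc[0].locus.chrom, rc[0].locus.start))
    deduped: list[tuple[LocusCluster, HairpinCandidate]] = []
    for cluster, cand in results:
        span = cand.window_span or (cluster.locus.start, cluster.locus.end)
        merged = False
        for i, (ocl, ocand) in enumerate(deduped):
            ospan = ocand.window_span or (ocl.locus.start, ocl.locus.end)
            if ocl.locus.chrom == cluster.locus.chrom and span[0] < ospan[1] and ospan[0] < span[1]:
                old_key = (ocand.star_supported, ocand.score, ocl.locus.strand == "+")
                new_key = (cand.star_supported, cand.score, cluster.locus.strand == "+")
                if new_key > old_key:
                    deduped[i] = (cluster, cand)
                merged = True
                break
        if not merged:
            deduped.append((cluster, cand))
    return deduped
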