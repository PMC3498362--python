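"""Synthetic reference, two-condition small-RNA libraries and degradome tags.

The generator emulates the study design every downstream stage expects: a
small genome carrying planted miRNA hairpin loci (mature + 8-nt loop +
reverse complement of the mature, so the excised precursor folds into a stem
meeting the discovery criteria without external folding software), structural
RNA loci (rRNA/tRNA/snRNA/snoRNA) and decoy loci emitting condition-balanced
background tags, a transcriptome with perfectly complementary planted target
sites, and degradome 5'-end tags peaking opposite miRNA position 10. Planted
log2 fold changes span both signs and zero (default palette covers the
-3.8 .. +2.5 range of realistic starvation responses); read counts are drawn
negative-binomial with variance mu + alpha * mu^2, so alpha = 0 degenerates to
deterministic counts that make every rate analytically checkable.

Everything derives from one integer seed: fixed seed, byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import revcomp
from .io import AnnotationRecord, GenomeLocus

HAIRPIN_LOOP = "AACAAGAA"  # 8-nt terminal loop spacer of planted hairpins
STRUCTURAL_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")


@dataclass(frozen=True)
class PlantedMiRNA:
    name: str
    mature: str
    locus: GenomeLocus
    log2fc: float
    star_planted: bool
    known: bool  # listed in the emitted mature-miRNA FASTA (not a discovery target)
    star_sequence: str
    precursor_locus: GenomeLocus


@dataclass
class SyntheticTruth:
    planted_mirnas: list[PlantedMiRNA]
    structural_loci: list[tuple[str, GenomeLocus]]
    decoy_loci: list[GenomeLocus]
    planted_targets: list[tuple[str, str, int, float]]  # (miRNA, transcript, start1, penalty)
    seed: int
    background_tags: list[str] = field(default_factory=list)

    def mirna(self, name: str) -> PlantedMiRNA:
        return next(m for m in self.planted_mirnas if m.name == name)

    @property
    def novel(self) -> list[PlantedMiRNA]:
        return [m for m in self.planted_mirnas if not m.known]

    @property
    def known(self) -> list[PlantedMiRNA]:
        return [m for m in self.planted_mirnas if m.known]


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 30_000
    n_novel_mirnas: int = 5
    n_known_mirnas: int = 3
    n_structural: int = 8
    n_decoys: int = 6
    n_transcripts: int = 8
    transcript_length: int = 600
    depth: int = 200_000  # expected clean reads per library (condition A)
    dispersion: float = 0.1  # NB alpha; variance mu + alpha mu^2
    mirna_base_mean: float = 200.0  # expected mature count in condition A
    star_fraction: float = 0.1  # star mean as a fraction of the mature mean
    fold_palette: tuple[float, ...] = (-3.8, -2.0, -1.4, 0.0, 0.5, 1.2, 2.0, 2.5)
    # explicit per-planted-miRNA effects (cycled); None -> cycle fold_palette
    planted_log2fc: tuple[float, ...] | None = None
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    truncate_adapters: bool = False  # emit reads whose adapter is cut at read_length
    read_length: int = 50
    tags_per_background_locus: int = 4
    background_locus_length: int = 120
    degradome_peak_count: int = 30
    degradome_noise_rate: float = 0.01  # per-position probability of a 1-count tag
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        pal = self.fold_palette
        if not (any(x > 0 for x in pal) and any(x < 0 for x in pal) and 0.0 in pal):
            raise ValueError("fold-change palette must include both signs and zero")
        if self.n_chromosomes < 1 or self.chromosome_length < 1000:
            raise ValueError("need at least one chromosome of >= 1 kb")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


_SLOT = 500  # genomic slot reserved per planted locus (cassette + fold flanks)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    """Negative binomial with variance mu + alpha mu^2; alpha=0 is deterministic."""
    if mean <= 0:
        return 0
    if alpha == 0:
        return int(round(mean))
    r = 1.0 / alpha
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def make_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[AnnotationRecord], dict[str, str], SyntheticTruth]:
    """Genome, annotations, transcriptome and planted truth for one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_mirnas = config.n_novel_mirnas + config.n_known_mirnas
    n_loci = n_mirnas + config.n_structural + config.n_decoys
    slots_per_chrom = (config.chromosome_length - _SLOT) // _SLOT
    if n_loci > slots_per_chrom * config.n_chromosomes:
        raise ValueError(
            f"chromosomes too short to host {n_loci} loci "
            f"({slots_per_chrom * config.n_chromosomes} slots available)"
        )

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {name: _random_seq(rng, config.chromosome_length) for name in chrom_names}

    all_slots = [
        (name, _SLOT // 2 + k * _SLOT)
        for name in chrom_names
        for k in range(slots_per_chrom)
    ]
    slot_idx = rng.permutation(len(all_slots))[:n_loci]
    slots = [all_slots[i] for i in sorted(slot_idx)]
    rng.shuffle(slots)

    def genome_has(seq: str) -> bool:
        rc = revcomp(seq)
        return any(seq in c or rc in c for c in chroms.values())

    # --- plant miRNA hairpins -------------------------------------------
    planted: list[PlantedMiRNA] = []
    matures: set[str] = set()
    length_choices = np.array([20, 21, 22, 23, 24])
    length_weights = np.array([0.15, 0.5, 0.15, 0.1, 0.1])
    palette = list(
        config.planted_log2fc if config.planted_log2fc is not None else config.fold_palette
    )
    for i in range(n_mirnas):
        known = i < config.n_known_mirnas
        name = f"mir{i + 1:03d}" if known else f"mirN{i - config.n_known_mirnas + 1:02d}"
        L = int(rng.choice(length_choices, p=length_weights))
        while True:
            mature = _random_seq(rng, L)
            if mature not in matures and not genome_has(mature):
                break
        matures.add(mature)
        chrom, pos = slots[i]
        strand = "+" if i % 2 == 0 else "-"
        cassette = mature + HAIRPIN_LOOP + revcomp(mature)
        inserted = cassette if strand == "+" else revcomp(cassette)
        seq = chroms[chrom]
        chroms[chrom] = seq[:pos] + inserted + seq[pos + len(inserted):]
        if strand == "+":
            locus = GenomeLocus(chrom, pos, pos + L, strand)
        else:
            locus = GenomeLocus(chrom, pos + len(cassette) - L, pos + len(cassette), strand)
        # star: 2-nt 3' overhangs on both duplex ends -> star spans the last
        # L-2 nt of the reverse-complement arm plus 2 nt of downstream flank
        flank = 20
        w0 = pos - flank
        w1 = pos + len(cassette) + flank
        window = chroms[chrom][w0:w1]
        rna = window if strand == "+" else revcomp(window)
        star_seq = rna[flank + L + len(HAIRPIN_LOOP) + 2 : flank + 2 * L + len(HAIRPIN_LOOP) + 2]
        precursor_locus = GenomeLocus(chrom, pos, pos + len(cassette), strand)
        planted.append(
            PlantedMiRNA(
                name=name,
                mature=mature,
                locus=locus,
                log2fc=float(palette[i % len(palette)]),
                star_planted=(i % 2 == 0),
                known=known,
                star_sequence=star_seq,
                precursor_locus=precursor_locus,
            )
        )

    # --- structural and decoy loci --------------------------------------
    annotations: list[AnnotationRecord] = []
    structural: list[tuple[str, GenomeLocus]] = []
    for j in range(config.n_structural):
        chrom, pos = slots[n_mirnas + j]
        strand = "+" if j % 2 == 0 else "-"
        cls = STRUCTURAL_CLASSES[j % len(STRUCTURAL_CLASSES)]
        locus = GenomeLocus(chrom, pos, pos + config.background_locus_length, strand)
        structural.append((cls, locus))
        annotations.append(
            AnnotationRecord(locus=locus, rna_class=cls, feature_id=f"{cls}_{j + 1}")
        )
    decoys: list[GenomeLocus] = []
    for j in range(config.n_decoys):
        chrom, pos = slots[n_mirnas + config.n_structural + j]
        strand = "+" if j % 2 == 0 else "-"
        decoys.append(GenomeLocus(chrom, pos, pos + config.background_locus_length, strand))

    # --- transcriptome with planted target sites -------------------------
    transcripts: dict[str, str] = {}
    planted_targets: list[tuple[str, str, int, float]] = []
    novel = [m for m in planted if not m.known]
    for t in range(config.n_transcripts):
        tid = f"AT{t + 1:02d}G{10 + t:02d}0"
        seq = _random_seq(rng, config.transcript_length)
        if t < len(novel):
            mir = novel[t]
            site = revcomp(mir.mature)
            start0 = int(rng.integers(50, config.transcript_length - len(site) - 50))
            seq = seq[:start0] + site + seq[start0 + len(site):]
            planted_targets.append((mir.name, tid, start0 + 1, 0.0))
        transcripts[tid] = seq

    # --- background tag pool (drawn once; identical in both conditions) ---
    # Decoy and structural loci must be genuinely non-hairpin contexts, but
    # random sequence occasionally contains an inverted repeat; tags with a
    # near-complementary partner in their neighbourhood are resampled so that
    # background never mimics a miRNA duplex.
    from .discover import best_duplex_diagonal

    background_tags: list[str] = []
    lengths = np.array([18, 19, 20, 21, 22, 23, 24, 25, 26, 28])
    weights = np.array([3, 10, 14, 22, 14, 18, 12, 3, 2, 2], dtype=float)
    weights /= weights.sum()
    for loc in [l for _, l in structural] + decoys:
        w0 = max(0, loc.start - 200)
        w1 = min(len(chroms[loc.chrom]), loc.end + 200)
        window = chroms[loc.chrom][w0:w1]
        if loc.strand == "-":
            window = revcomp(window)
        off0 = (loc.start - w0) if loc.strand == "+" else (w1 - loc.end)
        locus_len = loc.end - loc.start
        for _ in range(config.tags_per_background_locus):
            for _attempt in range(30):
                L = int(rng.choice(lengths, p=weights))
                start = off0 + int(rng.integers(0, locus_len - L + 1))
                tag = window[start : start + L]
                n_pairable, _ = best_duplex_diagonal(window, start, start + L)
                if n_pairable < L - 6:
                    break
            background_tags.append(tag)

    truth = SyntheticTruth(
        planted_mirnas=planted,
        structural_loci=structural,
        decoy_loci=decoys,
        planted_targets=planted_targets,
        seed=config.seed,
        background_tags=background_tags,
    )
    return chroms, annotations, transcripts, truth


def known_mature_fasta(truth: SyntheticTruth) -> dict[str, str]:
    """The mature sequences presented to quantification as 'known' miRNAs."""
    return {m.name: m.mature for m in truth.planted_mirnas if m.known}


def _emit(reads: list[str], seq: str, count: int, config: SimulationConfig) -> None:
    read = seq + config.adapter3
    if config.truncate_adapters:
        read = read[: config.read_length]
    reads.extend([read] * count)


def simulate_libraries(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[list[str], list[str]]:
    """Raw adapter-ligated reads for conditions A and B.

    Per planted miRNA, E[count_B] / E[count_A] = 2^log2fc; star reads are
    emitted only where star_planted; structural and decoy loci emit
    condition-balanced background whose expected total fills the configured
    depth in condition A.
    """
    config.validate()
    rng = np.random.default_rng((config.seed * 1_000_003 + 1) % 2**31)
    alpha = config.dispersion
    reads_a: list[str] = []
    reads_b: list[str] = []

    expected_a = 0.0
    for mir in truth.planted_mirnas:
        mean_a = config.mirna_base_mean
        mean_b = mean_a * 2.0 ** mir.log2fc
        _emit(reads_a, mir.mature, _nb_draw(rng, mean_a, alpha), config)
        _emit(reads_b, mir.mature, _nb_draw(rng, mean_b, alpha), config)
        expected_a += mean_a
        if mir.star_planted:
            star_a = max(2.0, config.star_fraction * mean_a)
            star_b = star_a * 2.0 ** mir.log2fc
            _emit(reads_a, mir.star_sequence, _nb_draw(rng, star_a, alpha), config)
            _emit(reads_b, mir.star_sequence, _nb_draw(rng, star_b, alpha), config)
            expected_a += star_a

    if truth.background_tags:
        bg_mean = max(0.0, (config.depth - expected_a) / len(truth.background_tags))
        for tag in truth.background_tags:
            # condition-balanced: same expected count in both libraries
            _emit(reads_a, tag, _nb_draw(rng, bg_mean, alpha), config)
            _emit(reads_b, tag, _nb_draw(rng, bg_mean, alpha), config)
    return reads_a, reads_b


def simulate_degradome(
    truth: SyntheticTruth,
    config: SimulationConfig,
    transcripts: dict[str, str],
) -> pd.DataFrame:
    """Degradome 5'-end tag table with peaks opposite miRNA position 10."""
    config.validate()
    if not truth.planted_targets:
        raise ValueError("truth has no planted targets")
    rng = np.random.default_rng((config.seed * 1_000_003 + 2) % 2**31)
    counts: dict[tuple[str, int], int] = {}
    for mir_name, tid, start1, _pen in truth.planted_targets:
        L = len(truth.mirna(mir_name).mature)
        pos = start1 + L - 10  # paired to miRNA position 10
        counts[(tid, pos)] = counts.get((tid, pos), 0) + config.degradome_peak_count
    if config.degradome_noise_rate > 0:
        for tid, seq in transcripts.items():
            hits = np.nonzero(rng.random(len(seq)) < config.degradome_noise_rate)[0]
            for p in hits:
                key = (tid, int(p) + 1)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"transcript": tid, "pos_1based": pos, "count": c}
        for (tid, pos), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["transcript", "pos_1based", "count"])


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Flat TSV view of the planted miRNAs."""
    rows = []
    for m in truth.planted_mirnas:
        rows.append(
            {
                "name": m.name,
                "mature": m.mature,
                "chrom": m.locus.chrom,
                "start0": m.locus.start,
                "end": m.locus.end,
                "strand": m.locus.strand,
                "log2fc": m.log2fc,
                "star_planted": m.star_planted,
                "known": m.known,
            }
        )
    return pd.DataFrame(rows)


def targets_frame(truth: SyntheticTruth) -> pd.DataFrame:
    return pd.DataFrame(
        truth.planted_targets,
        columns=["mirna", "transcript", "site_start1", "penalty"],
    )
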