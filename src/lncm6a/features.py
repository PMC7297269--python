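"""The 60 genomic features and the combined 144-value site encoding.

Feature groups (frozen catalog order):

====== ==========================================================
1-10   region topology dummies (exon/intron, first/internal/last
       exon, transcript halves, TSS/TES proximity, long exon)
11-12  distances to the 5'/3' splice junctions, capped at 2000 nt
13-14  log2 length of the containing region / of the mature transcript
15-32  one-hot identity of the DRACH 5-mer (lexicographic order)
33-36  candidate-motif clustering (counts in +/-50, 500, 2000 nt;
       distance to nearest other candidate, capped at 2000)
37-40  conservation: window means of two PhastCons-role and two
       fitCons-role score tracks (missing bases imputed as 0)
41-42  secondary structure of the 101-nt window: site base paired,
       paired fraction
43-55  m6A-biology interval-overlap dummies (configurable registry)
56     gene is a miRNA target
57-60  z-scores: isoform count, exon count, gene GC, local GC (101 nt)
====== ==========================================================

The sequence block (84 values, see :mod:`lncm6a.seq`) prepended to this
block gives the full 144-dimensional site representation.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import seq as seqmod
from .tracks import TrackBundle
from .transcripts import (
    Mode,
    TranscriptModel,
    containing_region_length,
    region_flags,
    REGION_FLAG_NAMES,
    select_longest_transcript,
    splice_junction_distances,
)

log = logging.getLogger(__name__)

CLUSTER_WINDOWS = (50, 500, 2000)
CLUSTER_DISTANCE_CAP = 2000
CONSERVATION_FLANK = 10     # 21-nt window
STRUCTURE_FLANK = 50        # 101-nt window
LOCAL_GC_FLANK = 50         # 101-nt window

SCORE_TRACK_NAMES = ["phastcons_1", "phastcons_2", "fitcons_1", "fitcons_2"]
ZSCORE_NAMES = ["isoform_num", "exon_num", "gc_gene", "gc_101"]


@dataclass(frozen=True)
class CandidateSite:
    """One adenosine under a DRACH motif.

    ``tx_pos`` is the 1-based coordinate on the owning transcript in the
    active mode; ``gpos`` the genomic 1-based coordinate of the A.
    """

    chrom: str
    gpos: int
    strand: str
    transcript_id: str
    gene_id: str
    tx_pos: int
    mode: Mode
    motif: str
    label: int | None = None

    @property
    def key(self) -> str:
        return f"{self.transcript_id}:{self.tx_pos}:{self.strand}"


class FeatureCatalog:
    """Frozen, ordered, named catalog of the 60 genomic features."""

    def __init__(self):
        names: list[str] = []
        groups: list[str] = []

        def add(block, group):
            names.extend(block)
            groups.extend([group] * len(block))

        add(REGION_FLAG_NAMES, "region")                          # 1-10
        add(["dist_sj_5_p2000", "dist_sj_3_p2000"], "splice")     # 11-12
        add(["log2_region_length", "log2_mature_length"], "length")  # 13-14
        add([f"motif_{m}" for m in seqmod.drach_motifs()], "motif")  # 15-32
        add(["cluster_n50", "cluster_n500", "cluster_n2000",
             "dist_nearest_p2000"], "cluster")                    # 33-36
        add(SCORE_TRACK_NAMES, "conservation")                    # 37-40
        add(["struct_site_paired", "struct_paired_fraction"],
            "structure")                                          # 41-42
        add([f"slot_{i}" for i in range(43, 56)], "overlap")      # 43-55
        add(["mirna_target"], "overlap")                          # 56
        add(ZSCORE_NAMES, "zscore")                               # 57-60
        assert len(names) == 60 and len(set(names)) == 60
        self.names = names
        self.groups = groups

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def full_names(self) -> list[str]:
        """Column names of the full 144-value matrix (sequence + genomic)."""
        offs = range(-seqmod.DEFAULT_WINDOW // 2 + 1,
                     seqmod.DEFAULT_WINDOW // 2 + 1)
        seq_names = [
            f"seq_p{o:+d}_{c}" for o in offs for c in ("x", "y", "z", "f")
        ]
        return seq_names + self.names

    def hash(self) -> str:
        return hashlib.sha256("\n".join(self.full_names).encode()).hexdigest()


DEFAULT_CATALOG = FeatureCatalog()


# ---------------------------------------------------------------------
# individual feature groups
# ---------------------------------------------------------------------

def region_length_features(model: TranscriptModel, site: int, mode) -> tuple[float, float]:
    """(log2 length of the containing exon/intron, log2 mature length)."""
    region_len = containing_region_length(model, site, mode)
    return math.log2(region_len), math.log2(model.mature_length)


def clustering_features(site: int, candidates, cap: int = CLUSTER_DISTANCE_CAP,
                        windows=CLUSTER_WINDOWS) -> tuple[int, int, int, int]:
    """Counts of other candidates within nested windows + nearest distance.

    ``candidates`` are the positions (active-mode coordinates) of all
    DRACH candidates on the same transcript, the site itself included or
    not; the site's own position is never counted.
    """
    others = np.asarray([c for c in candidates if c != site])
    if others.size == 0:
        return (0,) * len(windows) + (cap,)
    d = np.abs(others - site)
    counts = tuple(int((d <= w).sum()) for w in windows)
    return counts + (int(min(d.min(), cap)),)


def conservation_features(site: CandidateSite, model: TranscriptModel,
                          tracks: TrackBundle,
                          flank: int = CONSERVATION_FLANK) -> list[float]:
    """Window means of the four conservation score tracks.

    The window is taken in the site's coordinate mode and projected
    per-base to the genome (so in mature mode it may span introns on the
    genome side).  Missing values are imputed as 0 and counted.
    """
    n = model.length(site.mode)
    tx_positions = [p for p in range(site.tx_pos - flank, site.tx_pos + flank + 1)
                    if 1 <= p <= n]
    gpos = [model.transcript_to_genomic(p, site.mode) for p in tx_positions]
    out = []
    missing = 0
    for track in tracks.score_tracks:
        vals = track.values(site.chrom, gpos)
        missing += int(np.isnan(vals).sum())
        vals = np.nan_to_num(vals, nan=0.0)
        out.append(float(vals.mean()) if len(vals) else 0.0)
    if missing:
        log.debug("conservation window at %s: %d missing base values imputed as 0",
                  site.key, missing)
    return out


def structure_features(site: CandidateSite, model: TranscriptModel,
                       window_sequence: str, tracks: TrackBundle,
                       flank: int = STRUCTURE_FLANK) -> tuple[int, float]:
    """(site base paired, paired fraction) from the 101-nt window structure."""
    window_start = max(1, site.tx_pos - flank)
    key = f"{site.transcript_id}:{window_start}"
    db = tracks.structure.dot_bracket(key, window_sequence)
    if db is None:
        return 0, 0.0
    if len(db) != len(window_sequence):
        raise ValueError(
            f"structure for {key} has length {len(db)}, window {len(window_sequence)}"
        )
    center = site.tx_pos - window_start
    # window_sequence may be N-padded on the left when near the 5' end
    pad_left = len(window_sequence) - len(window_sequence.lstrip("N"))
    center += pad_left
    paired = int(db[center] in "()")
    frac = sum(c in "()" for c in db) / len(db)
    return paired, frac


def attribute_overlap_flags(site: CandidateSite, model: TranscriptModel,
                            tracks: TrackBundle) -> list[int]:
    """13 interval-overlap dummies + the gene-level miRNA-target dummy."""
    flags = [
        int(t.overlaps(site.chrom, site.gpos, site.strand))
        for t in tracks.interval_tracks
    ]
    s, e = model.span
    flags.append(
        int(tracks.mirna_targets.overlaps_range(site.chrom, s, e, site.strand))
    )
    return flags


@dataclass
class ZScoreStats:
    """Population (n-denominator) mean/sd for the four z-scored quantities."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @classmethod
    def fit(cls, gene_values: dict[str, dict[str, float]],
            local_gcs: list[float]) -> "ZScoreStats":
        """gene_values: {gene_id: {isoform_num, exon_num, gc_gene}}."""
        stats = cls()
        for name in ("isoform_num", "exon_num", "gc_gene"):
            vals = np.array([gv[name] for gv in gene_values.values()], dtype=float)
            stats.means[name] = float(vals.mean()) if vals.size else 0.0
            stats.sds[name] = float(vals.std()) if vals.size else 0.0
        gc = np.asarray(local_gcs, dtype=float)
        stats.means["gc_101"] = float(gc.mean()) if gc.size else 0.0
        stats.sds["gc_101"] = float(gc.std()) if gc.size else 0.0
        return stats

    def z(self, name: str, value: float) -> float:
        sd = self.sds.get(name, 0.0)
        if sd == 0.0:
            return 0.0
        return (value - self.means[name]) / sd


def zscore_features(values: dict[str, float], stats: ZScoreStats) -> list[float]:
    """z-scores of isoform count, exon count, gene GC, local GC."""
    return [stats.z(name, values[name]) for name in ZSCORE_NAMES]


def gc_fraction(sequence: str) -> float:
    """G+C fraction over unambiguous bases; 0 when none."""
    valid = [b for b in sequence.upper() if b in "ACGTU"]
    if not valid:
        return 0.0
    return sum(b in "GC" for b in valid) / len(valid)


# ---------------------------------------------------------------------
# extraction driver
# ---------------------------------------------------------------------

class FeatureExtractor:
    """Computes sequence + genomic feature vectors for candidate sites.

    Holds the genome, the per-gene transcript choice (longest mature
    isoform), the evidence tracks and the dataset-level z-score
    population; caches transcript sequences and candidate scans.
    """

    def __init__(self, genome: dict[str, str],
                 genes: dict[str, list[TranscriptModel]],
                 tracks: TrackBundle | None = None,
                 mode: Mode | str = Mode.FULL,
                 catalog: FeatureCatalog | None = None):
        self.genome = genome
        self.genes = genes
        self.tracks = tracks or TrackBundle.empty()
        self.mode = Mode(mode)
        self.catalog = catalog or DEFAULT_CATALOG
        self.chosen: dict[str, TranscriptModel] = {
            g: select_longest_transcript(txs) for g, txs in genes.items()
        }
        self.by_transcript: dict[str, TranscriptModel] = {
            t.transcript_id: t for t in self.chosen.values()
        }
        self._seq_cache: dict[str, str] = {}
        self._cand_cache: dict[str, list[int]] = {}
        self._gene_values: dict[str, dict[str, float]] | None = None
        self.zstats: ZScoreStats | None = None

    # --- sequences ----------------------------------------------------
    @staticmethod
    def _revcomp(dna: str) -> str:
        comp = str.maketrans("ACGTUN", "TGCAAN")
        return dna.translate(comp)[::-1]

    def transcript_sequence(self, model: TranscriptModel) -> str:
        """Sense-strand RNA sequence of the transcript in the active mode."""
        ck = f"{model.transcript_id}:{self.mode.value}"
        if ck in self._seq_cache:
            return self._seq_cache[ck]
        chrom_seq = self.genome[model.chrom]
        if self.mode is Mode.FULL:
            s, e = model.span
            dna = chrom_seq[s - 1 : e]
            if model.strand == "-":
                dna = self._revcomp(dna)
        else:
            parts = []
            for xs, xe in model.exons_5p_to_3p():
                part = chrom_seq[xs - 1 : xe]
                if model.strand == "-":
                    part = self._revcomp(part)
                parts.append(part)
            dna = "".join(parts)
        rna = seqmod.normalize_rna(dna)
        self._seq_cache[ck] = rna
        return rna

    def candidates(self, model: TranscriptModel) -> list[int]:
        """DRACH candidate positions on the transcript in the active mode."""
        ck = f"{model.transcript_id}:{self.mode.value}"
        if ck not in self._cand_cache:
            self._cand_cache[ck] = seqmod.scan_drach(self.transcript_sequence(model))
        return self._cand_cache[ck]

    def make_site(self, model: TranscriptModel, tx_pos: int,
                  label: int | None = None) -> CandidateSite:
        rna = self.transcript_sequence(model)
        motif = rna[tx_pos - 3 : tx_pos + 2]
        return CandidateSite(
            chrom=model.chrom,
            gpos=model.transcript_to_genomic(tx_pos, self.mode),
            strand=model.strand,
            transcript_id=model.transcript_id,
            gene_id=model.gene_id,
            tx_pos=tx_pos,
            mode=self.mode,
            motif=motif,
            label=label,
        )

    # --- z-score population --------------------------------------------
    def gene_values(self) -> dict[str, dict[str, float]]:
        if self._gene_values is None:
            vals = {}
            for gene_id, txs in self.genes.items():
                model = self.chosen[gene_id]
                s, e = model.span
                dna = self.genome[model.chrom][s - 1 : e]
                if model.strand == "-":
                    dna = self._revcomp(dna)
                vals[gene_id] = {
                    "isoform_num": float(len(txs)),
                    "exon_num": float(model.n_exons),
                    "gc_gene": gc_fraction(dna),
                }
            self._gene_values = vals
        return self._gene_values

    def local_gc(self, site: CandidateSite, model: TranscriptModel) -> float:
        rna = self.transcript_sequence(model)
        lo = max(0, site.tx_pos - 1 - LOCAL_GC_FLANK)
        hi = min(len(rna), site.tx_pos + LOCAL_GC_FLANK)
        return gc_fraction(rna[lo:hi])

    def fit_population(self, sites: list[CandidateSite]) -> ZScoreStats:
        """Fit the z-score population from the dataset's genes and sites."""
        local = [
            self.local_gc(s, self.by_transcript[s.transcript_id]) for s in sites
        ]
        self.zstats = ZScoreStats.fit(self.gene_values(), local)
        return self.zstats

    # --- vectors --------------------------------------------------------
    def genomic_vector(self, site: CandidateSite) -> np.ndarray:
        if self.zstats is None:
            raise RuntimeError("call fit_population() before extracting vectors")
        model = self.by_transcript[site.transcript_id]
        rna = self.transcript_sequence(model)

        values: list[float] = []
        values += region_flags(model, site.tx_pos, self.mode)              # 1-10
        values += splice_junction_distances(model, site.tx_pos, self.mode)  # 11-12
        values += region_length_features(model, site.tx_pos, self.mode)    # 13-14
        one_hot = [0.0] * 18
        one_hot[seqmod.motif_identity(site.motif)] = 1.0
        values += one_hot                                                   # 15-32
        values += clustering_features(site.tx_pos, self.candidates(model))  # 33-36
        values += conservation_features(site, model, self.tracks)           # 37-40
        win101 = seqmod.window_around(rna, site.tx_pos, STRUCTURE_FLANK, quiet=True)
        values += structure_features(site, model, win101, self.tracks)      # 41-42
        values += attribute_overlap_flags(site, model, self.tracks)         # 43-56
        gvals = dict(self.gene_values()[site.gene_id])
        gvals["gc_101"] = self.local_gc(site, model)
        values += zscore_features(gvals, self.zstats)                       # 57-60
        vec = np.asarray(values, dtype=float)
        assert vec.shape == (len(self.catalog),)
        return vec

    def sequence_vector(self, site: CandidateSite) -> np.ndarray:
        model = self.by_transcript[site.transcript_id]
        rna = self.transcript_sequence(model)
        window = seqmod.window_around(rna, site.tx_pos, seqmod.DEFAULT_WINDOW // 2)
        return seqmod.encode_window(window)

    def full_vector(self, site: CandidateSite) -> np.ndarray:
        return np.concatenate([self.sequence_vector(site), self.genomic_vector(site)])


def extract_genomic_vector(site: CandidateSite, extractor: FeatureExtractor) -> np.ndarray:
    """The 60-value genomic feature vector for one site."""
    return extractor.genomic_vector(site)
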