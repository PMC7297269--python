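"""Seeded synthetic genomes, annotations, tracks and replicate site calls.

The generator emulates the statistical structure of base-resolution m6A
replicate experiments: a genome carrying lncRNA-like genes (few exons,
shorter) and mRNA-like genes (more exons, longer); true methylated
adenosines planted on DRACH motifs with configurable biases (motif
preference, 3'-end positional enrichment, elevated conservation,
GC/structure context); and per-replicate call sets equal to the truth
minus random dropouts plus false calls at random unmethylated DRACH
positions.  Setting every effect size to zero yields label-independent
features, the null condition for classifier calibration checks.

All randomness flows from one integer seed through named child
generators, so identical configurations reproduce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GenomicSite, SiteCallSet
from .features import FeatureExtractor, gc_fraction
from .seq import write_fasta
from .tracks import (
    BedInterval,
    IntervalTrack,
    ScoreTrack,
    TrackBundle,
    write_bed,
    write_bedgraph,
)
from .transcripts import Mode, TranscriptModel

_PAPER_LNC_POSITIVES = 1291
_PAPER_MRNA_POSITIVES = 57105


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Effect sizes of 0 make every planted bias vanish; rates are
    probabilities in [0, 1].
    """

    seed: int = 20200609
    # gene architecture
    n_lnc_genes: int = 150
    n_mrna_genes: int = 150
    lnc_exons: tuple[int, int] = (2, 3)
    lnc_exon_len: tuple[int, int] = (400, 1600)
    mrna_exons: tuple[int, int] = (5, 9)
    mrna_exon_len: tuple[int, int] = (150, 450)
    intron_len: tuple[int, int] = (150, 700)
    intergenic_gap: tuple[int, int] = (300, 900)
    second_isoform_prob: float = 0.3
    gc_mean: dict = field(default_factory=lambda: {"lncRNA": 0.45, "mRNA": 0.52})
    gc_sd: float = 0.04
    # planted sites
    n_positives_lnc: int = 2000
    n_positives_mrna: int = 2000
    motif_weights: dict | None = None  # default: GGAC-core motifs 4x
    motif_weights_mrna: dict | None = None  # None -> same preference as lncRNA
    pos_bias_3p: float = 1.0
    conservation_effect: float = 0.25
    structure_bias: float = 0.5
    # replicate noise
    n_replicates: int = 6
    dropout: float = 0.15
    false_call_rate: float = 0.05

    def __post_init__(self):
        for name in ("dropout", "false_call_rate", "second_isoform_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def null(self) -> "FixtureConfig":
        """Copy with every planted effect removed (label-independent features)."""
        return replace(self, motif_weights={}, pos_bias_3p=0.0,
                       conservation_effect=0.0, structure_bias=0.0)


def default_motif_weights() -> dict[str, float]:
    """Preference for the canonical GGAC-core 5-mers (weight 4 vs 1)."""
    from .seq import drach_motifs

    return {m: 4.0 if m.startswith("GGAC") else 1.0 for m in drach_motifs()}


@dataclass
class Fixture:
    """In-memory fixture: genome, annotation, tracks, calls and truth."""

    config: FixtureConfig
    genome: dict[str, str]
    genes: dict[str, list[TranscriptModel]]       # all genes
    gene_class: dict[str, str]                    # gene_id -> lncRNA | mRNA
    call_sets: list[SiteCallSet]
    tracks: TrackBundle
    truth: pd.DataFrame                           # chrom pos strand gene class motif

    def genes_of(self, rna_class: str) -> dict[str, list[TranscriptModel]]:
        return {g: t for g, t in self.genes.items()
                if self.gene_class[g] == rna_class}

    def truth_sites(self, rna_class: str | None = None) -> set[GenomicSite]:
        df = self.truth
        if rna_class is not None:
            df = df[df["rna_class"] == rna_class]
        return {(r.chrom, int(r.pos), r.strand) for r in df.itertuples()}

    def write(self, out_dir) -> dict[str, Path]:
        return write_fixture(self, out_dir)


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------

_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BYTES[idx].tobytes().decode()


def _build_genes(cfg: FixtureConfig, rng: np.random.Generator):
    """Lay genes along one chromosome; returns (sequence, genes, classes)."""
    chrom = "chr1"
    seq_parts: list[str] = []
    pos = 1
    genes: dict[str, list[TranscriptModel]] = {}
    classes: dict[str, str] = {}

    specs = ([("lncRNA", i) for i in range(cfg.n_lnc_genes)]
             + [("mRNA", i) for i in range(cfg.n_mrna_genes)])
    for rna_class, i in specs:
        gap = int(rng.integers(*cfg.intergenic_gap))
        seq_parts.append(_random_dna(rng, gap, 0.45))
        pos += gap
        if rna_class == "lncRNA":
            n_ex = int(rng.integers(cfg.lnc_exons[0], cfg.lnc_exons[1] + 1))
            exon_len = cfg.lnc_exon_len
        else:
            n_ex = int(rng.integers(cfg.mrna_exons[0], cfg.mrna_exons[1] + 1))
            exon_len = cfg.mrna_exon_len
        gc = float(np.clip(rng.normal(cfg.gc_mean[rna_class], cfg.gc_sd),
                           0.25, 0.75))
        exons = []
        for k in range(n_ex):
            ln = int(rng.integers(*exon_len))
            exons.append((pos, pos + ln - 1))
            seq_parts.append(_random_dna(rng, ln, gc))
            pos += ln
            if k < n_ex - 1:
                iln = int(rng.integers(*cfg.intron_len))
                seq_parts.append(_random_dna(rng, iln, 0.42))
                pos += iln
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"{'LNC' if rna_class == 'lncRNA' else 'MRN'}{i:05d}"
        tid = f"{gid}.t1"
        txs = [TranscriptModel(tid, gid, chrom, strand, exons)]
        if len(exons) > 1 and rng.random() < cfg.second_isoform_prob:
            txs.append(TranscriptModel(f"{gid}.t2", gid, chrom, strand, exons[:-1]))
        genes[gid] = txs
        classes[gid] = rna_class
    seq_parts.append(_random_dna(rng, int(rng.integers(*cfg.intergenic_gap)), 0.45))
    return {chrom: "".join(seq_parts)}, genes, classes


def _candidate_table(extractor: FeatureExtractor, cfg: FixtureConfig,
                     gene_ids: list[str]) -> pd.DataFrame:
    """Every DRACH candidate on the chosen transcripts, with bias covariates."""
    rows = []
    for gid in gene_ids:
        model = extractor.chosen[gid]
        rna = extractor.transcript_sequence(model)
        length = len(rna)
        for tx_pos in extractor.candidates(model):
            gpos = model.transcript_to_genomic(tx_pos, Mode.FULL)
            lo = max(0, tx_pos - 51)
            rows.append({
                "gene_id": gid,
                "transcript_id": model.transcript_id,
                "chrom": model.chrom,
                "gpos": gpos,
                "strand": model.strand,
                "tx_pos": tx_pos,
                "motif": rna[tx_pos - 3 : tx_pos + 2],
                "relpos": tx_pos / length,
                "gc101": gc_fraction(rna[lo : tx_pos + 50]),
            })
    return pd.DataFrame(rows)


def _plant_positives(cands: pd.DataFrame, n: int, cfg: FixtureConfig,
                     rng: np.random.Generator,
                     weights: dict | None = None) -> pd.DataFrame:
    if n > len(cands):
        raise ValueError(
            f"requested {n} positives but only {len(cands)} DRACH candidates"
        )
    if weights is None:
        weights = cfg.motif_weights
    if weights is None:
        weights = default_motif_weights()
    w = cands["motif"].map(lambda m: weights.get(m, 1.0)).to_numpy(dtype=float)
    w = w * np.exp(cfg.pos_bias_3p * (cands["relpos"].to_numpy() - 0.5))
    w = w * np.exp(cfg.structure_bias * 2 * (cands["gc101"].to_numpy() - 0.5))
    idx = rng.choice(len(cands), size=n, replace=False, p=w / w.sum())
    return cands.iloc[np.sort(idx)].reset_index(drop=True)


def _conservation_tracks(cfg: FixtureConfig, genome: dict[str, str],
                         truth: pd.DataFrame, rng: np.random.Generator,
                         bin_width: int = 25) -> list[ScoreTrack]:
    """Four binned noise tracks; windows around positives are elevated."""
    tracks = []
    effect = (cfg.conservation_effect, cfg.conservation_effect,
              cfg.conservation_effect / 2, cfg.conservation_effect / 2)
    for t, name in enumerate(("phastcons_1", "phastcons_2",
                              "fitcons_1", "fitcons_2")):
        per_chrom = {}
        for chrom, seq in genome.items():
            n = len(seq)
            nbins = math.ceil(n / bin_width)
            vals = np.repeat(rng.beta(2.0, 5.0, size=nbins), bin_width)[:n]
            sub = truth[truth["chrom"] == chrom]
            for p in sub["gpos"].to_numpy():
                lo, hi = max(0, p - 11), min(n, p + 10)
                vals[lo:hi] += effect[t]
            per_chrom[chrom] = np.clip(vals, 0.0, 1.0).astype(np.float32)
        tracks.append(_array_to_track(per_chrom, name))
    return tracks


def _array_to_track(per_chrom: dict[str, np.ndarray], name: str) -> ScoreTrack:
    intervals = []
    for chrom, vals in per_chrom.items():
        change = np.r_[0, np.where(np.diff(vals) != 0)[0] + 1, len(vals)]
        for s, e in zip(change[:-1], change[1:]):
            intervals.append((chrom, int(s), int(e), round(float(vals[s]), 4)))
    return ScoreTrack.from_intervals(intervals, name)


def _interval_tracks(cfg: FixtureConfig, genes, classes,
                     rng: np.random.Generator) -> tuple[list[IntervalTrack], IntervalTrack]:
    """Two populated overlap tracks (rest empty) + gene-level miRNA targets."""
    slots = [IntervalTrack(f"slot_{i}") for i in range(43, 56)]
    for slot_idx in (0, 1):
        track = slots[slot_idx]
        for gid, txs in genes.items():
            if rng.random() < 0.25:
                model = txs[0]
                s, e = model.span
                mid = int(rng.integers(s, e + 1))
                half = int(rng.integers(25, 120))
                track.add(BedInterval(model.chrom, max(0, mid - half), mid + half,
                                      f"{track.name}_{gid}", 0, model.strand))
    mirna = IntervalTrack("mirna_targets")
    for gid, txs in genes.items():
        if rng.random() < 0.3:
            model = txs[0]
            s, e = model.span
            mirna.add(BedInterval(model.chrom, s - 1, e, gid, 0, model.strand))
    return slots, mirna


def _call_sets(cfg: FixtureConfig, truth: pd.DataFrame, cands: pd.DataFrame,
               rng: np.random.Generator) -> list[SiteCallSet]:
    truth_sites = [(r.chrom, int(r.gpos), r.strand) for r in truth.itertuples()]
    truth_set = set(truth_sites)
    other = cands[~cands.apply(
        lambda r: (r["chrom"], r["gpos"], r["strand"]) in truth_set, axis=1)]
    other_sites = [(r.chrom, int(r.gpos), r.strand) for r in other.itertuples()]
    n_false = round(cfg.false_call_rate * len(truth_sites))
    call_sets = []
    for rep in range(cfg.n_replicates):
        keep = rng.random(len(truth_sites)) >= cfg.dropout
        called = {s for s, k in zip(truth_sites, keep) if k}
        if n_false and other_sites:
            idx = rng.choice(len(other_sites), size=min(n_false, len(other_sites)),
                             replace=False)
            called |= {other_sites[i] for i in idx}
        call_sets.append(SiteCallSet(f"replicate_{rep + 1}", frozenset(called)))
    return call_sets


def generate_fixture(config: FixtureConfig | None = None) -> Fixture:
    """Generate the complete in-memory fixture for one configuration."""
    cfg = config or FixtureConfig()
    root = np.random.default_rng(cfg.seed)
    seeds = {name: int(s) for name, s in zip(
        ("genes", "plant", "tracks", "calls"),
        root.integers(0, 2**31 - 1, size=4))}

    genome, genes, classes = _build_genes(cfg, np.random.default_rng(seeds["genes"]))
    extractor = FeatureExtractor(genome, genes, mode=Mode.FULL)

    plant_rng = np.random.default_rng(seeds["plant"])
    truth_frames = []
    cand_frames = []
    for rna_class, n_pos in (("lncRNA", cfg.n_positives_lnc),
                             ("mRNA", cfg.n_positives_mrna)):
        gene_ids = sorted(g for g, c in classes.items() if c == rna_class)
        cands = _candidate_table(extractor, cfg, gene_ids)
        cand_frames.append(cands)
        weights = (cfg.motif_weights_mrna
                   if rna_class == "mRNA" and cfg.motif_weights_mrna is not None
                   else cfg.motif_weights)
        planted = _plant_positives(cands, n_pos, cfg, plant_rng, weights)
        planted = planted.assign(rna_class=rna_class)
        truth_frames.append(planted)
    truth = pd.concat(truth_frames, ignore_index=True)
    all_cands = pd.concat(cand_frames, ignore_index=True)

    score_tracks = _conservation_tracks(
        cfg, genome, truth, np.random.default_rng(seeds["tracks"]))
    slots, mirna = _interval_tracks(
        cfg, genes, classes, np.random.default_rng(seeds["tracks"] + 1))
    tracks = TrackBundle(score_tracks=score_tracks, interval_tracks=slots,
                         mirna_targets=mirna)

    call_sets = _call_sets(cfg, truth, all_cands,
                           np.random.default_rng(seeds["calls"]))

    truth_out = truth.rename(columns={"gpos": "pos"})[
        ["chrom", "pos", "strand", "gene_id", "transcript_id",
         "tx_pos", "motif", "rna_class"]
    ]
    return Fixture(config=cfg, genome=genome, genes=genes, gene_class=classes,
                   call_sets=call_sets, tracks=tracks, truth=truth_out)


def mimic_paper_scale(seed: int = 20200609, scale: float = 1.0) -> FixtureConfig:
    """Configuration emulating the published dataset-size imbalance.

    At scale 1 this plants ~1,291 lncRNA positives and a >20x larger
    mRNA positive set — the class imbalance that motivates blending an
    mRNA-trained model into the lncRNA predictor.  ``scale`` shrinks the
    whole design proportionally for desk-size runs.
    """
    n_lnc = max(10, round(_PAPER_LNC_POSITIVES * scale))
    n_mrna = max(220, round(_PAPER_MRNA_POSITIVES * scale))
    # ~50 DRACH / kb-scale lncRNA gene, ~85 / mRNA gene under the default
    # architecture; triple headroom keeps the negative pool feasible.
    return FixtureConfig(
        seed=seed,
        n_positives_lnc=n_lnc,
        n_positives_mrna=n_mrna,
        n_lnc_genes=max(20, math.ceil(n_lnc * 3 / 50)),
        n_mrna_genes=max(20, math.ceil(n_mrna * 3 / 85)),
    )


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def write_gtf(genes: dict[str, list[TranscriptModel]], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes):
            for model in genes[gid]:
                for s, e in model.exons:
                    attrs = (f'gene_id "{gid}"; '
                             f'transcript_id "{model.transcript_id}";')
                    fh.write(
                        f"{model.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t"
                        f"{model.strand}\t.\t{attrs}\n"
                    )


def write_fixture(fixture: Fixture, out_dir) -> dict[str, Path]:
    """Write FASTA, GTF, bedGraph x4, BED tracks, call-set BEDs and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = out / "genome.fa"
    write_fasta(sorted(fixture.genome.items()), paths["fasta"])
    paths["gtf"] = out / "annotation.gtf"
    write_gtf(fixture.genes, paths["gtf"])

    for track in fixture.tracks.score_tracks:
        p = out / f"{track.name}.bedGraph"
        intervals = []
        for chrom, (starts, ends, vals) in sorted(track._chrom.items()):
            intervals += [(chrom, int(s), int(e), float(v))
                          for s, e, v in zip(starts, ends, vals)]
        write_bedgraph(intervals, p)
        paths[track.name] = p
    for track in fixture.tracks.interval_tracks + [fixture.tracks.mirna_targets]:
        p = out / f"{track.name}.bed"
        write_bed(sorted(track.intervals(),
                         key=lambda iv: (iv.chrom, iv.start, iv.end)), p)
        paths[track.name] = p

    for cs in fixture.call_sets:
        p = out / f"{cs.experiment_id}.bed"
        ivs = [BedInterval(c, pos - 1, pos, cs.experiment_id, 0, strand)
               for c, pos, strand in sorted(cs.sites)]
        write_bed(ivs, p)
        paths[cs.experiment_id] = p

    paths["truth"] = out / "truth.tsv"
    fixture.truth.to_csv(paths["truth"], sep="\t", index=False)

    paths["gene_classes"] = out / "gene_classes.tsv"
    pd.DataFrame(
        sorted(fixture.gene_class.items()), columns=["gene_id", "rna_class"]
    ).to_csv(paths["gene_classes"], sep="\t", index=False)
    return paths


def load_fixture_dir(path) -> Fixture:
    """Reload a fixture written by :func:`write_fixture` from its directory."""
    from .seq import read_fasta
    from .transcripts import load_annotation

    root = Path(path)
    genome = read_fasta(root / "genome.fa")
    genes = load_annotation(root / "annotation.gtf")
    gene_class = dict(
        pd.read_csv(root / "gene_classes.tsv", sep="\t").itertuples(index=False)
    )
    score_tracks = [
        ScoreTrack.from_bedgraph(root / f"{name}.bedGraph", name)
        for name in ("phastcons_1", "phastcons_2", "fitcons_1", "fitcons_2")
    ]
    slots = [
        IntervalTrack.from_bed(root / f"slot_{i}.bed", f"slot_{i}")
        for i in range(43, 56)
    ]
    mirna = IntervalTrack.from_bed(root / "mirna_targets.bed", "mirna_targets")
    tracks = TrackBundle(score_tracks=score_tracks, interval_tracks=slots,
                         mirna_targets=mirna)
    call_sets = [
        SiteCallSet.from_bed(p, p.stem) for p in sorted(root.glob("replicate_*.bed"))
    ]
    truth = pd.read_csv(root / "truth.tsv", sep="\t")
    cfg_seed = FixtureConfig()  # original config is not serialized; keep defaults
    return Fixture(config=cfg_seed, genome=genome, genes=genes,
                   gene_class=gene_class, call_sets=call_sets, tracks=tracks,
                   truth=truth)
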