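"""Balanced labeled datasets from replicate base-resolution site calls.

Positives are adenosines called in at least ``min_support`` replicate
experiments (default 2) that sit under a DRACH motif; negatives are
sampled uniformly from the remaining DRACH adenosines on the transcripts
that carry positives.  Sites mappable to more than one gene are
excluded.  The mature-RNA dataset is derived from the full-transcript
one by keeping exonic positives, re-projecting them to spliced
coordinates, and re-sampling matched negatives from the exonic pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CandidateSite, FeatureExtractor
from .seq import is_drach, normalize_rna
from .transcripts import Mode

log = logging.getLogger(__name__)

DEFAULT_SEED = 20200609
GenomicSite = tuple[str, int, str]  # (chrom, 1-based position of the A, strand)


@dataclass(frozen=True)
class SiteCallSet:
    """One replicate experiment's base-resolution m6A calls."""

    experiment_id: str
    sites: frozenset[GenomicSite]

    @classmethod
    def from_bed(cls, path, experiment_id: str | None = None) -> "SiteCallSet":
        """Read single-base BED6 records (0-based half-open, strand required)."""
        sites = set()
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: BED6 with strand required")
                chrom, start, end, _, _, strand = parts[:6]
                if int(end) - int(start) != 1:
                    raise ValueError(f"{path}:{ln}: expected single-base interval")
                sites.add((chrom, int(start) + 1, strand))
        return cls(experiment_id or str(path), frozenset(sites))


def genomic_drach(genome: dict[str, str], chrom: str, pos: int, strand: str) -> bool:
    """Whether the genomic position is the central A of a sense-strand DRACH."""
    seq = genome.get(chrom, "")
    if not 3 <= pos <= len(seq) - 2:
        return False
    window = seq[pos - 3 : pos + 2]
    if strand == "-":
        comp = str.maketrans("ACGTUN", "TGCAAN")
        window = window.translate(comp)[::-1]
    return is_drach(normalize_rna(window))


def consensus_positives(call_sets: list[SiteCallSet], min_support: int = 2,
                        genome: dict[str, str] | None = None) -> set[GenomicSite]:
    """Sites called in >= min_support replicates, restricted to DRACH As."""
    if not call_sets:
        raise ValueError("no call sets supplied")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    counts: dict[GenomicSite, int] = {}
    for cs in call_sets:
        for site in cs.sites:
            counts[site] = counts.get(site, 0) + 1
    hits = {s for s, c in counts.items() if c >= min_support}
    if genome is not None:
        hits = {s for s in hits if genomic_drach(genome, *s)}
    return hits


@dataclass
class LabeledDataset:
    """Balanced positive/negative candidate sites with a train/test split."""

    mode: Mode
    rna_class: str
    sites: list[CandidateSite]
    split: dict[str, str] = field(default_factory=dict)  # site key -> train|test
    seed: int = DEFAULT_SEED

    @property
    def positives(self) -> list[CandidateSite]:
        return [s for s in self.sites if s.label == 1]

    @property
    def negatives(self) -> list[CandidateSite]:
        return [s for s in self.sites if s.label == 0]

    def subset(self, which: str) -> list[CandidateSite]:
        return [s for s in self.sites if self.split.get(s.key) == which]

    def labels(self, sites=None) -> np.ndarray:
        return np.array([s.label for s in (sites or self.sites)], dtype=int)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_key": [s.key for s in self.sites],
                "label": [s.label for s in self.sites],
                "split": [self.split.get(s.key, "") for s in self.sites],
                "mode": [s.mode.value for s in self.sites],
                "rna_class": self.rna_class,
            }
        )


def _assign_gene(extractor: FeatureExtractor, site: GenomicSite):
    """Owning longest transcript, or None if no gene / multiple genes."""
    chrom, pos, strand = site
    owners = [
        m for m in extractor.chosen.values()
        if m.chrom == chrom and m.strand == strand
        and m.span[0] <= pos <= m.span[1]
    ]
    if len(owners) != 1:
        if len(owners) > 1:
            log.debug("site %s maps to %d genes; excluded", site, len(owners))
        return None
    return owners[0]


def positives_to_candidates(extractor: FeatureExtractor,
                            positives: set[GenomicSite]) -> list[CandidateSite]:
    """Resolve genomic positives onto single-gene transcripts (active mode)."""
    out = []
    for site in sorted(positives):
        model = _assign_gene(extractor, site)
        if model is None:
            continue
        try:
            tx_pos = model.genomic_to_transcript(site[1], extractor.mode)
        except ValueError:
            continue  # intronic in mature mode
        cand = extractor.make_site(model, tx_pos, label=1)
        if not is_drach(cand.motif):
            log.debug("positive %s not DRACH on transcript; excluded", site)
            continue
        out.append(cand)
    return out


def sample_negatives(extractor: FeatureExtractor,
                     positives: list[CandidateSite], n: int, seed: int,
                     excluded_genomic: set[GenomicSite] | None = None
                     ) -> list[CandidateSite]:
    """n non-positive DRACH adenosines from the positives' transcripts.

    ``excluded_genomic`` removes further sites (e.g. every site called in
    any replicate) from the candidate pool.
    """
    excluded = set(excluded_genomic or set())
    pos_keys = {(s.chrom, s.gpos, s.strand) for s in positives}
    excluded |= pos_keys
    pool: list[CandidateSite] = []
    for tid in sorted({s.transcript_id for s in positives}):
        model = extractor.by_transcript[tid]
        for tx_pos in extractor.candidates(model):
            gpos = model.transcript_to_genomic(tx_pos, extractor.mode)
            if (model.chrom, gpos, model.strand) in excluded:
                continue
            pool.append(extractor.make_site(model, tx_pos, label=0))
    if len(pool) < n:
        raise ValueError(
            f"negative pool has {len(pool)} sites, need {n} "
            f"(deficit {n - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def build_dataset(call_sets: list[SiteCallSet], extractor: FeatureExtractor,
                  rna_class: str, min_support: int = 2,
                  seed: int = DEFAULT_SEED, exclude_any_called: bool = True,
                  train_fraction: float = 0.8) -> LabeledDataset:
    """Full pipeline: consensus -> gene assignment -> negatives -> split."""
    consensus = consensus_positives(call_sets, min_support, genome=extractor.genome)
    positives = positives_to_candidates(extractor, consensus)
    if not positives:
        raise ValueError("no usable positive sites after filtering")
    excluded = set()
    if exclude_any_called:
        for cs in call_sets:
            excluded |= cs.sites
    negatives = sample_negatives(extractor, positives, len(positives), seed,
                                 excluded_genomic=excluded)
    ds = LabeledDataset(
        mode=extractor.mode, rna_class=rna_class,
        sites=positives + negatives, seed=seed,
    )
    split_train_test(ds, fraction=train_fraction, seed=seed)
    return ds


def derive_mature_dataset(full_ds: LabeledDataset,
                          mature_extractor: FeatureExtractor,
                          seed: int | None = None) -> LabeledDataset:
    """Mature-mode dataset: exonic positives re-projected, negatives re-sampled."""
    if full_ds.mode is not Mode.FULL:
        raise ValueError("expected a full-transcript dataset")
    if mature_extractor.mode is not Mode.MATURE:
        raise ValueError("extractor must be in mature mode")
    seed = full_ds.seed if seed is None else seed
    genomic_pos = {(s.chrom, s.gpos, s.strand) for s in full_ds.positives}
    positives = positives_to_candidates(mature_extractor, genomic_pos)
    genomic_all = {(s.chrom, s.gpos, s.strand) for s in full_ds.sites}
    negatives = sample_negatives(mature_extractor, positives, len(positives),
                                 seed, excluded_genomic=genomic_all)
    ds = LabeledDataset(
        mode=Mode.MATURE, rna_class=full_ds.rna_class,
        sites=positives + negatives, seed=seed,
    )
    split_train_test(ds, seed=seed)
    return ds


def split_train_test(dataset: LabeledDataset, fraction: float = 0.8,
                     seed: int | None = None) -> tuple[list, list]:
    """Stratified random train/test partition, recorded on the dataset."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    seed = dataset.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    for label in (1, 0):
        group = [s for s in dataset.sites if s.label == label]
        order = rng.permutation(len(group))
        n_train = round(fraction * len(group))
        for rank, i in enumerate(order):
            split[group[i].key] = "train" if rank < n_train else "test"
    dataset.split = split
    return dataset.subset("train"), dataset.subset("test")


def build_feature_matrix(dataset: LabeledDataset, extractor: FeatureExtractor,
                         sites=None) -> tuple[pd.DataFrame, np.ndarray]:
    """144-column feature matrix (84 sequence + 60 genomic) + labels.

    The z-score population is fitted on the whole dataset once; rows keep
    dataset order and are indexed by site key.
    """
    if extractor.zstats is None:
        extractor.fit_population(dataset.sites)
    sites = dataset.sites if sites is None else sites
    rows = [extractor.full_vector(s) for s in sites]
    X = pd.DataFrame(
        rows, columns=extractor.catalog.full_names, index=[s.key for s in sites]
    )
    y = np.array([s.label for s in sites], dtype=int)
    return X, y


def write_manifest(dataset: LabeledDataset, path) -> None:
    dataset.manifest().to_csv(path, sep="\t", index=False)
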