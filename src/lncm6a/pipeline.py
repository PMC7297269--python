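"""End-to-end driver: calls -> datasets -> features -> models -> ensemble.

Builds the lncRNA and mRNA datasets from replicate call sets, trains one
random forest per RNA class, selects the ensemble weight alpha on a
validation split carved from the lncRNA training data (never the test
set), and evaluates the lncRNA-trained, mRNA-trained and blended
predictors on the held-out lncRNA test sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as met
from .datasets import (
    DEFAULT_SEED,
    LabeledDataset,
    SiteCallSet,
    build_dataset,
    build_feature_matrix,
    derive_mature_dataset,
)
from .features import FeatureExtractor
from .model import (
    ALPHA_GRID,
    EnsemblePredictor,
    RandomForestConfig,
    ensemble_probability,
    predict_probability,
    select_alpha_from_probs,
    train_classifier,
)
from .tracks import TrackBundle
from .transcripts import Mode, TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    mode: Mode
    alpha: float
    alpha_curve: dict[float, float]
    report_lnc: met.EvaluationReport
    report_mrna: met.EvaluationReport
    report_ensemble: met.EvaluationReport
    dataset_lnc: LabeledDataset
    dataset_mrna: LabeledDataset
    predictions: pd.DataFrame  # test-site probabilities and calls
    ensemble: EnsemblePredictor

    def summary(self) -> str:
        rows = [
            ("mRNA trained", self.report_mrna),
            ("lncRNA trained", self.report_lnc),
            (f"Ensemble (alpha={self.alpha:.1f})", self.report_ensemble),
        ]
        lines = [
            f"lncRNA m6A site prediction — {self.mode.value} mode",
            "=" * 60,
            f"lncRNA sites: {len(self.dataset_lnc.sites)} "
            f"({len(self.dataset_lnc.positives)} positive)",
            f"mRNA sites:   {len(self.dataset_mrna.sites)} "
            f"({len(self.dataset_mrna.positives)} positive)",
            "-" * 60,
            f"{'predictor':<24s}{'Sn':>7s}{'Sp':>7s}{'ACC':>7s}{'MCC':>7s}{'AUC':>7s}",
        ]
        for name, r in rows:
            lines.append(
                f"{name:<24s}{r.sn:>7.3f}{r.sp:>7.3f}{r.acc:>7.3f}"
                f"{r.mcc:>7.3f}{r.auc:>7.3f}"
            )
        return "\n".join(lines)


def _carve_validation(keys: list[str], fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_val = max(1, round(fraction * len(keys)))
    val = set(order[-n_val:])
    train = [keys[i] for i in sorted(set(range(len(keys))) - val)]
    return train, [keys[i] for i in sorted(val)]


def _build_class_dataset(call_sets, genome, genes, tracks, mode, seed,
                         rna_class, min_support):
    full_extractor = FeatureExtractor(genome, genes, tracks, Mode.FULL)
    ds = build_dataset(call_sets, full_extractor, rna_class,
                       min_support=min_support, seed=seed)
    if Mode(mode) is Mode.MATURE:
        mat_extractor = FeatureExtractor(genome, genes, tracks, Mode.MATURE)
        ds = derive_mature_dataset(ds, mat_extractor)
        return ds, mat_extractor
    return ds, full_extractor


def run_pipeline(call_sets: list[SiteCallSet], genome: dict[str, str],
                 genes: dict[str, list[TranscriptModel]],
                 gene_class: dict[str, str],
                 tracks: TrackBundle | None = None,
                 mode: Mode | str = Mode.FULL,
                 seed: int = DEFAULT_SEED,
                 rf_config: RandomForestConfig | None = None,
                 min_support: int = 2,
                 validation_fraction: float = 0.2,
                 grid=ALPHA_GRID) -> PipelineResult:
    """Run the full prediction workflow for one coordinate mode."""
    mode = Mode(mode)
    tracks = tracks or TrackBundle.empty()
    rf_config = rf_config or RandomForestConfig(seed=seed % (2**31))

    genes_lnc = {g: t for g, t in genes.items() if gene_class[g] == "lncRNA"}
    genes_mrna = {g: t for g, t in genes.items() if gene_class[g] == "mRNA"}
    ds_lnc, ex_lnc = _build_class_dataset(
        call_sets, genome, genes_lnc, tracks, mode, seed, "lncRNA", min_support)
    ds_mrna, ex_mrna = _build_class_dataset(
        call_sets, genome, genes_mrna, tracks, mode, seed + 1, "mRNA", min_support)
    log.info("datasets built: lncRNA %d sites, mRNA %d sites (%s mode)",
             len(ds_lnc.sites), len(ds_mrna.sites), mode.value)

    X_lnc, y_lnc = build_feature_matrix(ds_lnc, ex_lnc)
    X_mrna, y_mrna = build_feature_matrix(ds_mrna, ex_mrna)

    train_keys = [s.key for s in ds_lnc.subset("train")]
    fit_keys, val_keys = _carve_validation(train_keys, validation_fraction, seed)
    test_keys = [s.key for s in ds_lnc.subset("test")]
    label_of = {s.key: s.label for s in ds_lnc.sites}

    def _xy(keys):
        return X_lnc.loc[keys], np.array([label_of[k] for k in keys])

    X_fit, y_fit = _xy(fit_keys)
    X_val, y_val = _xy(val_keys)
    X_test, y_test = _xy(test_keys)

    mrna_train = [s.key for s in ds_mrna.subset("train")]
    clf_lnc = train_classifier(X_fit, y_fit, rf_config)
    clf_mrna = train_classifier(
        X_mrna.loc[mrna_train],
        np.array([s.label for s in ds_mrna.subset("train")]),
        rf_config,
    )

    alpha, curve = select_alpha_from_probs(
        predict_probability(clf_mrna, X_val),
        predict_probability(clf_lnc, X_val),
        y_val, grid,
    )
    ensemble = EnsemblePredictor(clf_mrna, clf_lnc, alpha)

    p_lnc = predict_probability(clf_lnc, X_test)
    p_mrna = predict_probability(clf_mrna, X_test)
    p_en = ensemble_probability(p_mrna, p_lnc, alpha)

    predictions = pd.DataFrame(
        {
            "site_key": test_keys,
            "label": y_test,
            "p_lnc": p_lnc,
            "p_mrna": p_mrna,
            "p_ensemble": p_en,
            "call": (p_en > met.DEFAULT_THRESHOLD).astype(int),
        }
    )
    return PipelineResult(
        mode=mode,
        alpha=alpha,
        alpha_curve=curve,
        report_lnc=met.evaluate(y_test, p_lnc),
        report_mrna=met.evaluate(y_test, p_mrna),
        report_ensemble=met.evaluate(y_test, p_en),
        dataset_lnc=ds_lnc,
        dataset_mrna=ds_mrna,
        predictions=predictions,
        ensemble=ensemble,
    )


def scan_transcriptome(extractor: FeatureExtractor, predictor=None,
                       threshold: float = met.DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Every DRACH candidate on the extractor's transcripts, optionally scored.

    Returns transcript and genomic coordinates per candidate; with a
    fitted predictor also the probability and the binary call at the
    threshold (strictly greater-than).
    """
    sites = []
    for gid in sorted(extractor.chosen):
        model = extractor.chosen[gid]
        for tx_pos in extractor.candidates(model):
            sites.append(extractor.make_site(model, tx_pos))
    frame = pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in sites],
            "gene_id": [s.gene_id for s in sites],
            "tx_pos": [s.tx_pos for s in sites],
            "chrom": [s.chrom for s in sites],
            "gpos": [s.gpos for s in sites],
            "strand": [s.strand for s in sites],
            "motif": [s.motif for s in sites],
        }
    )
    if predictor is not None and len(sites):
        if extractor.zstats is None:
            extractor.fit_population(sites)
        X = np.stack([extractor.full_vector(s) for s in sites])
        probs = predictor.predict(X)
        frame["probability"] = probs
        frame["call"] = (probs > threshold).astype(int)
    return frame
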