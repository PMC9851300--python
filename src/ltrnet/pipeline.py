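"""End-to-end orchestration: cycles, score combination and IOU-based
non-maximal suppression.

The pipeline runs one to five analysis cycles.  Each cycle tiles every
sequence into non-overlapping windows (cycle ``c`` shifts the tiling by
``floor(W*c/C)`` bases), one-hot encodes them, keeps the windows the
detector scores above threshold, locates structural candidates inside
them, extracts convolutional k-mer features for each candidate, applies
the intactness filter (curation) and the lineage classifier, and pools
every cycle's predictions.  Overlapping predictions (IOU > 0.6) are then
reduced to the highest-scoring one, where a prediction's score is the
mean of its three network probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_io import (
    PREDICTIONS_FILENAME,
    GenomeSequence,
    OneHotWindow,
    WindowSpec,
    one_hot_encode,
    read_genome,
    split_windows,
    write_library,
    write_predictions_table,
)
from .kmer_conv import build_filter_bank, count_kmers_conv
from .neural_models import ModelBundle, detect_windows, predict_element
from .structural_candidates import (
    CandidateElement,
    StructuralParams,
    apply_structural_filters,
    find_candidates,
)


@dataclass
class Prediction:
    """A candidate with its three network probabilities and lineage call."""

    candidate: CandidateElement
    detect_prob: float
    intact_prob: float
    lineage: str
    lineage_prob: float
    cycle_index: int = 0

    @property
    def combined_score(self) -> float:
        return (self.detect_prob + self.intact_prob + self.lineage_prob) / 3.0

    # coordinate accessors used by the writers
    @property
    def source_id(self) -> str:
        return self.candidate.source_id

    @property
    def start(self) -> int:
        return self.candidate.start

    @property
    def end(self) -> int:
        return self.candidate.end

    @property
    def length(self) -> int:
        return self.end - self.start


def iou(x0: int, x1: int, y0: int, y1: int) -> float:
    """Intersection over union of two interval predictions.

    ``max(0, min(Y1, X1) - max(Y0, X0)) / (max(Y1, X1) - min(Y0, X0))``;
    symmetric in the two intervals, 0 for disjoint, 1 for identical.
    """
    if x1 <= x0 or y1 <= y0:
        raise ValueError("zero-length interval")
    inter = max(0, min(y1, x1) - max(y0, x0))
    union = max(y1, x1) - min(y0, x0)
    return inter / union


def non_maximal_suppression(
    preds: list[Prediction], iou_threshold: float = 0.6
) -> list[Prediction]:
    """Greedy score-descending suppression of overlapping predictions.

    Ties on the combined score prefer the longer element, then the smaller
    start.  A prediction is kept iff its IOU with every already-kept
    prediction on the same source sequence is <= the threshold.
    """
    ranked = sorted(
        preds, key=lambda p: (-p.combined_score, -(p.end - p.start), p.start, p.source_id)
    )
    kept: list[Prediction] = []
    for p in ranked:
        if all(
            q.source_id != p.source_id
            or iou(p.start, p.end, q.start, q.end) <= iou_threshold
            for q in kept
        ):
            kept.append(p)
    kept.sort(key=lambda p: (p.source_id, p.start))
    return kept


def _assign_window_prob(c: CandidateElement, scored: list) -> float:
    """Detection probability of an external candidate: the best probability
    among cycle-0 windows overlapping it."""
    best = 0.0
    for w, prob, _ in scored:
        if w.source_id == c.source_id and c.start < w.end and w.start < c.end:
            best = max(best, prob)
    return best


def run_pipeline(
    genome,
    bundle: ModelBundle,
    params: StructuralParams | None = None,
    cycles: int = 1,
    curation: bool = True,
    outdir=None,
    detect_threshold: float = 0.5,
    intact_threshold: float = 0.5,
    iou_threshold: float = 0.6,
    candidates: list[CandidateElement] | None = None,
    threads: int = 1,
) -> list[Prediction]:
    """Run detection, curation and classification over a genome assembly.

    ``genome`` is a FASTA path or a list of :class:`GenomeSequence`.  With
    ``curation=True`` elements whose intact probability falls below
    ``intact_threshold`` are dropped.  If ``candidates`` is given the
    built-in structural finder is bypassed and the supplied elements are
    scored directly (single cycle).  When ``outdir`` is set, the FASTA
    library and the predictions table are written there.  The run is
    deterministic given genome, bundle and parameters.
    """
    if bundle is None:
        raise ValueError("missing model bundle")
    if not 1 <= cycles <= 5:
        raise ValueError("cycles must be in [1, 5]")
    params = params or StructuralParams()
    seqs: list[GenomeSequence] = genome if isinstance(genome, list) else read_genome(genome)
    W = bundle.window_size
    if not any(g.length >= W for g in seqs):
        raise ValueError("assembly too short: no sequence spans one window")

    bank = build_filter_bank()
    preds: list[Prediction] = []

    def score_candidates(cands: list[CandidateElement], g: GenomeSequence, cycle: int):
        for c in cands:
            # clip any overrun into padding / sequence edge
            c.start, c.end = max(0, c.start), min(g.length, c.end)
            vec = count_kmers_conv(_encode_element(g, c), bank)
            intact_prob, lineage, lineage_prob = predict_element(bundle, vec)
            if curation and intact_prob < intact_threshold:
                continue
            preds.append(
                Prediction(
                    candidate=c, detect_prob=c.detect_prob, intact_prob=intact_prob,
                    lineage=lineage, lineage_prob=lineage_prob, cycle_index=cycle,
                )
            )

    if candidates is not None:
        scored_windows = []
        for g in seqs:
            spec = WindowSpec(window_size=W, cycle_index=0, total_cycles=1)
            wins = [one_hot_encode(g, s, e, W) for s, e in split_windows(g, spec)]
            scored_windows.extend(detect_windows(bundle.detector, wins, detect_threshold))
        by_id = {g.id: g for g in seqs}
        for c in candidates:
            c.detect_prob = _assign_window_prob(c, scored_windows)
        filtered = apply_structural_filters(candidates, seqs, params)
        for c in filtered:
            score_candidates([c], by_id[c.source_id], 0)
    else:
        for cycle in range(cycles):
            for g in seqs:
                spec = WindowSpec(window_size=W, cycle_index=cycle, total_cycles=cycles)
                coords = split_windows(g, spec)
                wins = [one_hot_encode(g, s, e, W) for s, e in coords]
                scored = detect_windows(bundle.detector, wins, detect_threshold)
                for w, prob, keep in scored:
                    if not keep:
                        continue
                    cands = find_candidates(
                        g.seq[w.start : w.end], params,
                        genome_offset=w.start, source_id=g.id, detect_prob=prob,
                    )
                    cands = apply_structural_filters(cands, g, params)
                    score_candidates(cands, g, cycle)

    final = non_maximal_suppression(preds, iou_threshold)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_library(final, seqs, outdir / "ltrnet_library.fasta")
        write_predictions_table(final, outdir / PREDICTIONS_FILENAME)
    return final


def _encode_element(g: GenomeSequence, c: CandidateElement) -> OneHotWindow:
    return one_hot_encode(g, c.start, c.end)


# ----------------------------------------------- synthetic bundle training


def train_synthetic_bundle(
    seed: int = 0,
    window_size: int = 50_000,
    n_detect_windows: int = 200,
    detector_epochs: int = 40,
    n_intact: int = 1000,
    n_defective: int = 1000,
    n_per_lineage: int = 40,
    fnn_epochs: int = 100,
    n_components: int = 64,
    outdir=None,
) -> ModelBundle:
    """Train a complete model bundle on synthetic data.

    The corpus sizes and epoch counts default to a configuration that
    trains in minutes on one CPU; the per-network configs keep their
    published defaults for every hyper-parameter not overridden here.
    """
    import numpy as np

    from .genome_io import encode_sequence
    from .kmer_conv import kmer_matrix
    from .neural_models import (
        ClassifierConfig,
        DEFAULT_LINEAGES,
        DetectorConfig,
        FilterConfig,
        fit_preprocessor,
        train_classifier,
        train_detector,
        train_filter,
    )
    from .synthetic_data import gen_filter_set, gen_lineage_set, gen_training_windows

    bank = build_filter_bank()
    rng = np.random.default_rng(seed)
    s_det, s_fil, s_cls = (int(rng.integers(0, 2**31 - 1)) for _ in range(3))

    w_seqs, w_labels, _ = gen_training_windows(
        n_detect_windows // 2, n_detect_windows - n_detect_windows // 2,
        window_size=window_size, seed=s_det,
    )
    X_windows = np.stack([encode_sequence(s) for s in w_seqs])
    # slim conv pyramid, small batches and a global final pool: the dense
    # head then sees position-invariant features, which is what lets a
    # modest window corpus generalise at full 50 kb width on CPU
    det_cfg = DetectorConfig(
        window_size=window_size, epochs=detector_epochs, lr=0.01,
        conv_filters=(16, 32, 64), pool=(10, 10, 0), batch_size=16,
    )
    detector, det_hist = train_detector(X_windows, w_labels, det_cfg, seed=s_det)

    f_seqs, f_labels, _ = gen_filter_set(n_intact, n_defective, seed=s_fil)
    c_seqs, c_labels = gen_lineage_set(n_per_lineage, seed=s_cls)
    feats_all = kmer_matrix(f_seqs + c_seqs, bank)
    pre = fit_preprocessor(feats_all, n_components=n_components, seed=seed)

    fil_cfg = FilterConfig(epochs=fnn_epochs)
    filt, fil_hist = train_filter(pre.transform(feats_all[: len(f_seqs)]), f_labels,
                                  fil_cfg, seed=s_fil)
    cls_cfg = ClassifierConfig(epochs=fnn_epochs)
    clf, cls_hist = train_classifier(pre.transform(feats_all[len(f_seqs):]), c_labels,
                                     cls_cfg, seed=s_cls)

    bundle = ModelBundle(
        detector=detector, preprocessor=pre, filter=filt, classifier=clf,
        lineages=list(DEFAULT_LINEAGES), window_size=window_size,
        metadata={
            "seed": seed,
            "training": "synthetic lineage-model corpus",
            "val_accuracy": {
                "detector": det_hist["val_accuracy"],
                "filter": fil_hist["val_accuracy"],
                "classifier": cls_hist["val_accuracy"],
            },
        },
    )
    if outdir is not None:
        bundle.save(outdir)
    return bundle
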