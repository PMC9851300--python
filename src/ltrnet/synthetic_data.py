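"""Seeded synthetic genomes, elements and training corpora.

Every generator emulates the statistical structure the networks are
trained on in production use:

* 13 lineage models, each an order-2 Markov chain over {A,C,G,T} with its
  own stationary composition (so 6-mer profiles separate lineages), a
  narrow element-length envelope and an LTR-length range;
* intact elements built as LTR + internal + LTR with TG...CA termini and a
  configurable 2% LTR divergence;
* genomic background from a separate near-uniform Markov model;
* implantation with 4-6 bp target-site duplications copied from the host
  flank;
* non-intact decoys of three kinds: nested LTR-RT insertions, length
  violations beyond +/-20% of the lineage envelope, and Class II-like
  terminal-inverted-repeat cassette insertions.

All outputs are deterministic given the seed and coordinate-consistent
with the emitted sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import WINDOW_SIZE, GenomeSequence
from .neural_models import DEFAULT_LINEAGES

_BASES = "ACGT"
_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed master seed of the default lineage model set; the default models
#: are a constant of the package, independent of user seeds.
_MODEL_SEED = 717_171

#: Tolerance on the lineage length envelope used for the intactness labels.
LENGTH_TOLERANCE = 0.20


@dataclass
class LineageModel:
    """An order-2 Markov composition model for one lineage."""

    name: str
    trans: np.ndarray  # (16, 4) row-stochastic, state = 4*prev2 + prev1
    ltr_len_range: tuple[int, int]
    element_len_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        self._cum = np.cumsum(self.trans, axis=1)

    def length_envelope(self, tolerance: float = LENGTH_TOLERANCE) -> tuple[float, float]:
        lo, hi = self.element_len_range
        return lo * (1 - tolerance), hi * (1 + tolerance)


@dataclass
class SyntheticTruth:
    """Ground truth for one implanted or generated element."""

    source_id: str
    start: int
    end: int
    lineage: str
    intact: bool = True
    defect: str = "none"  # none | nested | length_violation | class2_insert
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    tsd: str | None = None
    straddles: int | None = None  # window boundary crossed, if deliberate


def _stationary_base_dist(trans: np.ndarray) -> np.ndarray:
    """Stationary single-base distribution of an order-2 chain."""
    # state (a, b) -> (b, c) with probability trans[4a+b, c]
    P = np.zeros((16, 16))
    for s in range(16):
        b = s % 4
        for c in range(4):
            P[s, 4 * b + c] = trans[s, c]
    pi = np.full(16, 1 / 16)
    for _ in range(200):
        pi = pi @ P
    return np.array([pi[np.arange(16) % 4 == c].sum() for c in range(4)])


def _random_transition(rng: np.random.Generator, bias_conc: float = 6.0) -> np.ndarray:
    """A random order-2 transition table biased toward one stationary
    composition (shared across rows), giving each model a distinct k-mer
    signature while keeping genuine order-2 structure.

    Draws are rejected until the stationary base composition is at least
    0.15 total-variation away from uniform: element composition must be
    distinguishable from the near-uniform genomic background, otherwise
    window-level detection is ill-posed by construction.
    """
    while True:
        base = rng.dirichlet(np.ones(4) * 1.2)
        rows = rng.dirichlet(base * bias_conc + 0.3, size=16)
        trans = rows / rows.sum(axis=1, keepdims=True)
        if 0.5 * np.abs(_stationary_base_dist(trans) - 0.25).sum() >= 0.15:
            return trans


def default_lineage_models() -> list[LineageModel]:
    """The 13 default lineage models (deterministic constants)."""
    models = []
    for i, name in enumerate(DEFAULT_LINEAGES):
        rng = np.random.default_rng(_MODEL_SEED + i)
        center = 3000 + 500 * i  # 3000 .. 9000 bp, inside the [2000, 28000] envelope
        ltr = 300 + 60 * i
        models.append(
            LineageModel(
                name=name,
                trans=_random_transition(rng),
                ltr_len_range=(ltr, ltr + 100),
                element_len_range=(center - 200, center + 200),
            )
        )
    return models


def background_model() -> LineageModel:
    """Near-uniform order-2 model emulating non-repeat genomic background."""
    rng = np.random.default_rng(_MODEL_SEED - 1)
    rows = rng.dirichlet(np.ones(4) * 40.0, size=16)
    return LineageModel(
        name="background", trans=rows / rows.sum(axis=1, keepdims=True),
        ltr_len_range=(0, 0), element_len_range=(0, 0),
    )


def class2_model() -> LineageModel:
    """Composition model for Class II-like (TIR) decoy cassettes."""
    rng = np.random.default_rng(_MODEL_SEED - 2)
    return LineageModel(
        name="class2", trans=_random_transition(rng, bias_conc=4.0),
        ltr_len_range=(0, 0), element_len_range=(0, 0),
    )


# ------------------------------------------------------------- sampling


def markov_sample(model: LineageModel, length: int, rng: np.random.Generator) -> str:
    """Sample one sequence (scalar chain loop; cheap per-base)."""
    if length <= 0:
        return ""
    if length <= 2:
        return "".join(_BASES[c] for c in rng.integers(0, 4, size=length))
    cum = getattr(model, "_cum_rows", None)
    if cum is None:
        cum = [tuple(row) for row in model._cum]
        model._cum_rows = cum
    u = rng.random(length)
    out = bytearray(length)
    c0 = int(4 * u[0]) if u[0] < 1 else 3
    c1 = int(4 * u[1]) if u[1] < 1 else 3
    out[0], out[1] = _BYTES[c0], _BYTES[c1]
    state = c0 * 4 + c1
    bases = bytes(_BYTES)
    for t in range(2, length):
        row = cum[state]
        x = u[t]
        nxt = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[t] = bases[nxt]
        state = (state % 4) * 4 + nxt
    return out.decode("ascii")


def markov_sample_batch(
    model: LineageModel, lengths: list[int], rng: np.random.Generator
) -> list[str]:
    """Sample many sequences at once (vectorised across sequences)."""
    n = len(lengths)
    if n == 0:
        return []
    L = max(lengths)
    codes = np.zeros((n, max(L, 2)), dtype=np.int8)
    codes[:, 0] = rng.integers(0, 4, size=n)
    codes[:, 1] = rng.integers(0, 4, size=n)
    cum = model._cum
    state = codes[:, 0].astype(np.int64) * 4 + codes[:, 1]
    u = rng.random((n, max(L - 2, 0)))
    for t in range(2, L):
        nxt = (u[:, t - 2 : t - 1] > cum[state]).sum(axis=1)
        codes[:, t] = nxt
        state = (state % 4) * 4 + nxt
    arr = _BYTES[codes]
    return [arr[i, : lengths[i]].tobytes().decode("ascii") for i in range(n)]


def _mutate(seq: str, rate: float, rng: np.random.Generator, protect: int = 2) -> str:
    """Substitute bases at the given rate, protecting both termini."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    hit = np.flatnonzero(rng.random(n) < rate)
    hit = hit[(hit >= protect) & (hit < n - protect)]
    for i in hit:
        choices = [b for b in _BYTES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


@dataclass
class ElementRecord:
    seq: str
    lineage: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]


def gen_element(
    model: LineageModel,
    seed=0,
    ltr_divergence: float = 0.02,
    max_element_len: int | None = None,
) -> ElementRecord:
    """Generate one intact element: LTR + internal + diverged LTR copy.

    Both LTRs start TG and end CA; the 3' copy carries ``ltr_divergence``
    substitutions (termini protected).  ``seed`` may be an int or a
    Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = model.element_len_range
    if max_element_len is not None:
        hi = min(hi, max_element_len)
        lo = min(lo, hi)
        if hi < 2 * model.ltr_len_range[0] + 200:
            raise ValueError(f"element of lineage {model.name} cannot fit in {max_element_len} bp")
    elem_len = int(rng.integers(lo, hi + 1))
    llo, lhi = model.ltr_len_range
    lhi = min(lhi, (elem_len - 200) // 2)
    ltr_len = int(rng.integers(llo, max(llo, lhi) + 1))
    internal_len = elem_len - 2 * ltr_len
    ltr = "TG" + markov_sample(model, ltr_len - 4, rng) + "CA"
    internal = markov_sample(model, internal_len, rng)
    ltr2 = _mutate(ltr, ltr_divergence, rng)
    return ElementRecord(
        seq=ltr + internal + ltr2,
        lineage=model.name,
        ltr5=(0, ltr_len),
        ltr3=(elem_len - ltr_len, elem_len),
    )


# -------------------------------------------------------------- windows


def _implant(
    bg: str, elem: ElementRecord, pos: int, tsd_len: int
) -> tuple[str, SyntheticTruth]:
    """Insert an element into background at ``pos``, duplicating the
    ``tsd_len`` host bases left of the insertion site on the right flank."""
    tsd = bg[pos - tsd_len : pos]
    seq = bg[:pos] + elem.seq + tsd + bg[pos:]
    truth = SyntheticTruth(
        source_id="", start=pos, end=pos + len(elem.seq), lineage=elem.lineage,
        ltr5=(pos + elem.ltr5[0], pos + elem.ltr5[1]),
        ltr3=(pos + elem.ltr3[0], pos + elem.ltr3[1]),
        tsd=tsd,
    )
    return seq, truth


def gen_window(
    target: bool,
    window_size: int = WINDOW_SIZE,
    seed=0,
    models: list[LineageModel] | None = None,
    lineage: str | None = None,
) -> tuple[str, SyntheticTruth | None]:
    """One training window: background only, or with a single implant.

    Target windows contain exactly one element at a uniform random
    position with a 4-6 bp TSD on both flanks.  Lineages whose elements
    cannot fit the window are excluded from the draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    models = models or default_lineage_models()
    bg_model = background_model()
    if not target:
        return markov_sample(bg_model, window_size, rng), None
    margin = 50
    max_elem = window_size - 2 * margin - 10  # room for flanks and the TSD copy
    fit = [
        m for m in models
        if 2 * m.ltr_len_range[0] + 200 <= max_elem and m.element_len_range[0] <= max_elem
    ]
    if lineage is not None:
        fit = [m for m in fit if m.name == lineage]
    if not fit:
        raise ValueError("element longer than window")
    model = fit[rng.integers(0, len(fit))]
    elem = gen_element(model, rng, max_element_len=max_elem)
    tsd_len = int(rng.integers(4, 7))
    bg = markov_sample(bg_model, window_size - len(elem.seq) - tsd_len, rng)
    pos = int(rng.integers(margin, len(bg) - margin + 1))
    seq, truth = _implant(bg, elem, pos, tsd_len)
    return seq, truth


def gen_training_windows(
    n_target: int,
    n_background: int,
    window_size: int = WINDOW_SIZE,
    seed: int = 0,
    models: list[LineageModel] | None = None,
) -> tuple[list[str], np.ndarray, list[SyntheticTruth | None]]:
    """Balanced detector training corpus (label 1 = contains an element)."""
    rng = np.random.default_rng(seed)
    seqs, labels, truths = [], [], []
    for _ in range(n_target):
        s, t = gen_window(True, window_size, rng, models)
        seqs.append(s)
        labels.append(1)
        truths.append(t)
    bg_model = background_model()
    for s in markov_sample_batch(bg_model, [window_size] * n_background, rng):
        seqs.append(s)
        labels.append(0)
        truths.append(None)
    return seqs, np.asarray(labels, dtype=np.int64), truths


# ----------------------------------------------------- filter training set


def _defect_nested(models, rng) -> tuple[str, str]:
    a, b = rng.choice(len(models), size=2, replace=False)
    outer = gen_element(models[a], rng)
    inner = gen_element(models[b], rng)
    pos = int(rng.integers(outer.ltr5[1], outer.ltr3[0]))
    return outer.seq[:pos] + inner.seq + outer.seq[pos:], models[a].name


def _defect_length(models, rng) -> tuple[str, str]:
    m = models[rng.integers(0, len(models))]
    elem = gen_element(m, rng)
    if rng.random() < 0.5:  # truncate to 60% of true length
        keep = int(0.6 * len(elem.seq))
        return elem.seq[:keep], m.name
    extra = markov_sample(m, int(0.5 * len(elem.seq)), rng)  # extend to 150%
    cut = elem.ltr3[0]
    return elem.seq[:cut] + extra + elem.seq[cut:], m.name


def _defect_class2(models, rng) -> tuple[str, str]:
    m = models[rng.integers(0, len(models))]
    elem = gen_element(m, rng)
    c2 = class2_model()
    tir = markov_sample(c2, 20, rng)
    body = markov_sample(c2, int(rng.integers(460, 1961)), rng)
    rc = tir.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    cassette = tir + body + rc
    pos = int(rng.integers(elem.ltr5[1], elem.ltr3[0]))
    return elem.seq[:pos] + cassette + elem.seq[pos:], m.name


_DEFECTS = {
    "nested": _defect_nested,
    "length_violation": _defect_length,
    "class2_insert": _defect_class2,
}


def gen_filter_set(
    n_intact: int,
    n_defective: int,
    seed: int = 0,
    models: list[LineageModel] | None = None,
) -> tuple[list[str], np.ndarray, list[SyntheticTruth]]:
    """Intactness-filter training corpus (label 0 = intact, 1 = non-intact).

    Defects are drawn uniformly from the three kinds: nested LTR-RT
    insertion, length violation beyond the +/-20% lineage envelope
    (truncation to 60% or extension to 150%), and Class II-like cassette
    insertion.
    """
    if n_intact < 1 or n_defective < 1:
        raise ValueError("need at least one sequence of each class")
    rng = np.random.default_rng(seed)
    models = models or default_lineage_models()
    seqs, labels, truths = [], [], []
    for i in range(n_intact):
        m = models[i % len(models)]
        elem = gen_element(m, rng)
        seqs.append(elem.seq)
        labels.append(0)
        truths.append(SyntheticTruth("", 0, len(elem.seq), m.name, True, "none",
                                     elem.ltr5, elem.ltr3))
    kinds = list(_DEFECTS)
    for _ in range(n_defective):
        kind = kinds[rng.integers(0, len(kinds))]
        seq, lineage = _DEFECTS[kind](models, rng)
        seqs.append(seq)
        labels.append(1)
        truths.append(SyntheticTruth("", 0, len(seq), lineage, False, kind))
    return seqs, np.asarray(labels, dtype=np.int64), truths


def gen_lineage_set(
    n_per_lineage: int,
    seed: int = 0,
    models: list[LineageModel] | None = None,
) -> tuple[list[str], list[str]]:
    """Classifier training corpus: intact elements with lineage labels."""
    rng = np.random.default_rng(seed)
    models = models or default_lineage_models()
    seqs, labels = [], []
    for m in models:
        for _ in range(n_per_lineage):
            seqs.append(gen_element(m, rng).seq)
            labels.append(m.name)
    return seqs, labels


# --------------------------------------------------------------- genomes


def gen_genome(
    length: int = 500_000,
    n_implants: int = 10,
    seed: int = 0,
    straddle: bool = False,
    n_sequences: int = 1,
    models: list[LineageModel] | None = None,
    window_size: int = WINDOW_SIZE,
    spacing: int = 1000,
) -> tuple[list[GenomeSequence], list[SyntheticTruth]]:
    """A synthetic assembly with non-overlapping intact implants.

    Implants are spread over equal slots of each sequence (>= ``spacing``
    apart); with ``straddle=True`` one implant is centred on a
    ``window_size`` multiple so that single-cycle windowing splits it.
    Lineages are assigned round-robin.
    """
    rng = np.random.default_rng(seed)
    models = models or default_lineage_models()
    bg_model = background_model()
    genomes, truths = [], []
    for s_idx in range(n_sequences):
        sid = f"seq{s_idx + 1}"
        slot = length // n_implants
        if slot < max(m.element_len_range[1] for m in models) + 4 * spacing:
            raise ValueError("infeasible packing: implants do not fit with required spacing")
        elements = [gen_element(models[i % len(models)], rng) for i in range(n_implants)]
        boundary = None
        straddle_idx = None
        if straddle:
            # middle window boundary, at the start of some slot
            boundary = (length // window_size // 2) * window_size
            straddle_idx = min(boundary // slot, n_implants - 1)
        starts = []
        for i, elem in enumerate(elements):
            lo = i * slot + spacing
            hi = (i + 1) * slot - len(elem.seq) - 2 * spacing
            if straddle_idx is not None:
                if i == straddle_idx:
                    starts.append(boundary - len(elem.seq) // 2)
                    continue
                if i == straddle_idx - 1:
                    hi = min(hi, boundary - len(elements[straddle_idx].seq) // 2
                             - len(elem.seq) - 2 * spacing)
                if i == straddle_idx + 1:
                    lo = max(lo, boundary + len(elements[straddle_idx].seq) // 2 + 2 * spacing)
            if hi < lo:
                raise ValueError("infeasible packing: implants do not fit with required spacing")
            starts.append(int(rng.integers(lo, hi + 1)))
        order = np.argsort(starts)
        parts: list[str] = []
        cur = 0
        for i in order:
            elem, s0 = elements[i], starts[i]
            tsd_len = int(rng.integers(4, 7))
            bg = markov_sample(bg_model, s0 - cur, rng)
            parts.append(bg)
            parts.append(elem.seq)
            parts.append(bg[-tsd_len:])
            truths.append(
                SyntheticTruth(
                    source_id=sid, start=s0, end=s0 + len(elem.seq),
                    lineage=elem.lineage,
                    ltr5=(s0 + elem.ltr5[0], s0 + elem.ltr5[1]),
                    ltr3=(s0 + elem.ltr3[0], s0 + elem.ltr3[1]),
                    tsd=bg[-tsd_len:],
                    straddles=boundary if i == straddle_idx else None,
                )
            )
            cur = s0 + len(elem.seq) + tsd_len
        parts.append(markov_sample(bg_model, length - cur, rng))
        genomes.append(GenomeSequence(id=sid, seq="".join(parts)))
    return genomes, truths


def truth_to_tsv(truths: list[SyntheticTruth], path) -> None:
    """Write ground-truth records as TSV (1-based inclusive coordinates)."""
    cols = ["source_id", "start", "end", "lineage", "intact", "defect", "tsd", "straddles"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write(
                f"{t.source_id}\t{t.start + 1}\t{t.end}\t{t.lineage}\t"
                f"{int(t.intact)}\t{t.defect}\t{t.tsd or '.'}\t{t.straddles or '.'}\n"
            )


def write_fasta(seqs, path, ids=None) -> None:
    """Write sequences (strings or GenomeSequence) as unwrapped FASTA."""
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            if isinstance(s, GenomeSequence):
                fh.write(f">{s.id}\n{s.seq}\n")
            else:
                name = ids[i] if ids else f"seq{i + 1}"
                fh.write(f">{name}\n{s}\n")
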