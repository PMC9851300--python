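"""Structural candidate finding: paired long terminal repeats inside
detector-positive windows.

The finder is a transparent seed-and-extend direct-repeat search: exact
seed matches (20-mers by default) at a compatible spacing are clustered by
diagonal, greedily extended outward while the repeat-pair mismatch
fraction stays below a threshold, snapped to the canonical TG...CA termini
when present, and filtered by the structural rules (element length
envelope, TG/CA motif, target-site duplication).  Intact LTR pairs are
near-identical, which is what makes exact seeding effective.

An adapter ingests externally produced candidate tables (BED-like TSV) so
any third-party structural detector can replace the built-in finder.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

from .genome_io import GenomeSequence


@dataclass
class StructuralParams:
    """Structural filter settings.

    ``min_len``/``max_len`` bound the full element span (CLI flags -m/-M);
    ``require_tg_ca`` (-i) and ``require_tsd`` (-d) toggle the motif and
    target-site-duplication filters.
    """

    min_len: int = 2000
    max_len: int = 28000
    require_tg_ca: bool = True
    require_tsd: bool = True
    tsd_len_range: tuple[int, int] = (4, 6)
    seed_len: int = 20
    max_ltr_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if self.tsd_len_range[0] > self.tsd_len_range[1]:
            raise ValueError("empty tsd_len_range")


@dataclass
class CandidateElement:
    """A putative LTR-RT in genome coordinates (0-based half-open)."""

    source_id: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    tsd_seq: str | None = None
    tg_ca_ok: bool = False
    detect_prob: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start


# ------------------------------------------------------------- finding

_MAX_SEED_OCCURRENCES = 30  # skip low-complexity seeds
_CLUSTER_GAP = 1000
_MOTIF_SLOP = 30  # bp searched around raw boundaries for TG / CA termini


_MAX_RUN_MM = 4  # consecutive mismatches that terminate extension


def _extend_pair(seq: str, i0: int, i1: int, d: int, max_frac: float) -> tuple[int, int]:
    """Greedily extend the repeat block [i0, i1) (left copy) vs the copy at
    diagonal ``d``, keeping the mismatch fraction within ``max_frac``.

    Extension in a direction also stops after ``_MAX_RUN_MM`` consecutive
    mismatches: once outside the true repeat only ~1/4 of positions match
    by chance, so a short mismatch run marks the boundary, while inside a
    weakly diverged LTR pair such runs are vanishingly rare.  Returns the
    extended (start, end) of the left copy.
    """
    n = len(seq)
    s, e = i0, i1
    # each direction carries its own mismatch budget so that junk creep on
    # one side cannot starve genuine extension on the other
    mm = run = 0
    while e + d < n and (e + 1) - s <= d and run < _MAX_RUN_MM:
        a, b = seq[e], seq[e + d]
        if a == "N" or b == "N":
            break
        new_mm = mm + (a != b)
        if new_mm > max_frac * (e - s + 1):
            break
        run = run + 1 if a != b else 0
        mm, e = new_mm, e + 1
    mm = run = 0
    while s > 0 and e - (s - 1) <= d and run < _MAX_RUN_MM:
        a, b = seq[s - 1], seq[s - 1 + d]
        if a == "N" or b == "N":
            break
        new_mm = mm + (a != b)
        if new_mm > max_frac * (e - s + 1):
            break
        run = run + 1 if a != b else 0
        mm, s = new_mm, s - 1
    # trim mismatching termini so both boundaries sit on matching bases
    while s < e and seq[s] != seq[s + d]:
        s += 1
    while e > s and seq[e - 1] != seq[e - 1 + d]:
        e -= 1
    return s, e


def _snap_motif(
    seq: str, s: int, e: int, d: int, tsd_len_range: tuple[int, int] = (4, 6)
) -> tuple[int, int, bool]:
    """Snap LTR boundaries to TG...CA termini present in both copies.

    Among all TG starts / CA ends within the slop, a pair whose implied
    element boundaries show an abutting target-site duplication is
    preferred (insertion leaves one, and it pins the exact boundary);
    otherwise the pair closest to the raw extension boundaries wins.
    """
    n = len(seq)
    tg = [
        j
        for j in range(max(0, s - _MOTIF_SLOP), min(e - 2, s + _MOTIF_SLOP) + 1)
        if j + d + 2 <= n and seq[j : j + 2] == "TG" and seq[j + d : j + d + 2] == "TG"
    ]
    ca = [
        j
        for j in range(max(s + 2, e - _MOTIF_SLOP), min(n - d, e + _MOTIF_SLOP) + 1)
        if seq[j - 2 : j] == "CA" and seq[j - 2 + d : j + d] == "CA"
    ]
    if not tg or not ca:
        return s, e, False

    lo, hi = tsd_len_range

    def has_tsd(js: int, je: int) -> bool:
        start, end = js, je + d
        for L in range(hi, lo - 1, -1):
            if start - L >= 0 and end + L <= n:
                left = seq[start - L : start]
                if left == seq[end : end + L] and "N" not in left:
                    return True
        return False

    pairs = sorted(
        (abs(js - s) + abs(je - e), js, je) for js in tg for je in ca if je >= js + 4
    )
    for _, js, je in pairs:
        if has_tsd(js, je):
            return js, je, True
    if has_tsd(s, e):
        # raw boundaries carry insertion evidence; a motif pair without a
        # TSD would be a spurious interior TG/CA — keep the raw element
        return s, e, False
    if not pairs:
        return s, e, False
    _, js, je = pairs[0]
    return js, je, True


def find_candidates(
    window_seq: str,
    params: StructuralParams | None = None,
    genome_offset: int = 0,
    source_id: str = "",
    detect_prob: float = 1.0,
) -> list[CandidateElement]:
    """Locate paired direct repeats in one window and apply the filters.

    Coordinates of the returned candidates are genome-space
    (``genome_offset`` + window-local).  An empty list is a valid result.
    """
    params = params or StructuralParams()
    seq = window_seq.upper()
    n = len(seq)
    k = params.seed_len
    if n < params.min_len:
        return []

    # 1. exact-seed index
    seed_pos: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        s = seq[i : i + k]
        if "N" in s:
            continue
        seed_pos.setdefault(s, []).append(i)

    # 2. compatible seed pairs grouped by diagonal (distance between copies)
    diag_seeds: dict[int, list[int]] = {}
    for positions in seed_pos.values():
        if len(positions) < 2 or len(positions) > _MAX_SEED_OCCURRENCES:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                d = j - i
                if d < 100 or d + k > params.max_len:
                    continue
                diag_seeds.setdefault(d, []).append(i)

    # 3. cluster seeds per diagonal; extend each cluster from its longest
    #    run of consecutive seeds (a block that matches exactly by
    #    construction, so the extension's mismatch count starts at zero)
    raw: list[tuple[int, int, int]] = []  # (ltr_start, ltr_end, diagonal)

    def _flush(cluster: list[int], d: int) -> None:
        run_s = best_s = cluster[0]
        prev = best_e = cluster[0]
        for i in cluster[1:]:
            if i != prev + 1:
                run_s = i
            prev = i
            if i - run_s > best_e - best_s:
                best_s, best_e = run_s, i
        s, e = _extend_pair(seq, best_s, best_e + k, d, params.max_ltr_mismatch_frac)
        if e > s:
            raw.append((s, e, d))

    for d, starts in diag_seeds.items():
        starts = sorted(set(starts))
        cluster = [starts[0]]
        for i in starts[1:] + [starts[-1] + 10 * _CLUSTER_GAP]:
            if i - cluster[-1] <= _CLUSTER_GAP:
                cluster.append(i)
                continue
            _flush(cluster, d)
            cluster = [i]

    # 4. motif snap, length filter, longest-extension-first overlap resolution
    raw.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    accepted: list[CandidateElement] = []
    for s, e, d in raw:
        s2, e2, motif_ok = _snap_motif(seq, s, e, d, params.tsd_len_range)
        if motif_ok:
            s, e = s2, e2
        if params.require_tg_ca and not motif_ok:
            continue
        elem_start, elem_end = s, e + d
        if not (params.min_len <= elem_end - elem_start <= params.max_len):
            continue
        if any(elem_start < c.end - genome_offset and c.start - genome_offset < elem_end
               for c in accepted):
            continue
        accepted.append(
            CandidateElement(
                source_id=source_id,
                start=genome_offset + elem_start,
                end=genome_offset + elem_end,
                ltr5=(genome_offset + s, genome_offset + e),
                ltr3=(genome_offset + s + d, genome_offset + e + d),
                tg_ca_ok=motif_ok,
                detect_prob=detect_prob,
            )
        )
    accepted.sort(key=lambda c: c.start)
    return accepted


# ------------------------------------------------------------- filters


def _seq_of(genome, source_id: str) -> str:
    if isinstance(genome, GenomeSequence):
        return genome.seq
    if isinstance(genome, str):
        return genome
    for g in genome:
        if g.id == source_id:
            return g.seq
    raise ValueError(f"unknown source sequence {source_id!r}")


def check_motif(c: CandidateElement, genome) -> bool:
    """True iff both LTR copies start with TG and end with CA."""
    seq = _seq_of(genome, c.source_id)
    ok = True
    for a, b in (c.ltr5, c.ltr3):
        ok &= seq[a : a + 2] == "TG" and seq[b - 2 : b] == "CA"
    return ok


def check_tsd(
    c: CandidateElement, genome, tsd_len_range: tuple[int, int] = (4, 6)
) -> str | None:
    """The longest exact 4-6 bp duplication abutting the element, if any.

    Compares the suffix of the left flank with the prefix of the right
    flank; at the sequence edge there is no flank, so the result is absent
    (not an error).
    """
    seq = _seq_of(genome, c.source_id)
    lo, hi = tsd_len_range
    for L in range(hi, lo - 1, -1):
        if c.start - L < 0 or c.end + L > len(seq):
            continue
        left = seq[c.start - L : c.start]
        right = seq[c.end : c.end + L]
        if left == right and "N" not in left:
            return left
    return None


def apply_structural_filters(
    cands: Iterable[CandidateElement], genome, params: StructuralParams
) -> list[CandidateElement]:
    """Annotate motif/TSD evidence and drop candidates failing enabled checks."""
    out = []
    for c in cands:
        c.tg_ca_ok = check_motif(c, genome)
        c.tsd_seq = check_tsd(c, genome, params.tsd_len_range)
        if params.require_tg_ca and not c.tg_ca_ok:
            continue
        if params.require_tsd and c.tsd_seq is None:
            continue
        if not (params.min_len <= c.length <= params.max_len):
            continue
        out.append(c)
    return out


# -------------------------------------------------------------- adapter

_TSV_COLUMNS = ("source_id", "start", "end", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end")


def load_candidates_tsv(path, genome) -> list[CandidateElement]:
    """Read an external candidate table (1-based inclusive coordinates).

    Expected tab-separated columns: ``source_id start end ltr5_start
    ltr5_end ltr3_start ltr3_end``; a header row matching these names is
    permitted and skipped.  Rows are validated against the assembly and
    converted to internal 0-based half-open coordinates.
    """
    lengths = {g.id: g.length for g in genome}
    out: list[CandidateElement] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if ln == 1 and row[0] == _TSV_COLUMNS[0]:
                continue
            if len(row) < 7:
                raise ValueError(f"line {ln}: expected 7 columns, got {len(row)}")
            src = row[0]
            try:
                s1, e1, l5s, l5e, l3s, l3e = (int(v) for v in row[1:7])
            except ValueError as exc:
                raise ValueError(f"line {ln}: non-integer coordinate ({exc})") from None
            if src not in lengths:
                raise ValueError(f"line {ln}: unknown source sequence {src!r}")
            if s1 < 1 or e1 < s1:
                raise ValueError(f"line {ln}: invalid interval {s1}..{e1}")
            if e1 > lengths[src]:
                raise ValueError(f"line {ln}: interval {s1}..{e1} outside {src!r}")
            if not (s1 <= l5s <= l5e <= l3s <= l3e <= e1):
                raise ValueError(f"line {ln}: LTR coordinates inconsistent with element")
            out.append(
                CandidateElement(
                    source_id=src, start=s1 - 1, end=e1,
                    ltr5=(l5s - 1, l5e), ltr3=(l3s - 1, l3e),
                )
            )
    return out
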