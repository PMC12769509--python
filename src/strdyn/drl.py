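"""Distributions of repeat tract lengths (DRLs).

The central object of the package: for a motif class, the genome-wide
histogram of lengths (in complete units) of contiguous, uninterrupted
repeat tracts.  Tracts are counted with *maximal-region* semantics: a
repeated region is any maximal stretch with period equal to the unit
length, it is counted once per motif class, and its length is the maximum
number of complete units over the phase offsets (= floor(region_nt /
unit_length)).  Single units (L = 1) that are not extendable by a full
in-phase unit on either side are included.  Counts are pooled over all
members of a motif class (cyclic permutations and reverse complements),
so e.g. the unit-length-1 class "A" pools runs of A and runs of T.

Non-motif ("B") histograms record the lengths of maximal stretches in
which no member of the class occurs; they are needed by the dynamical
model, which tracks the B-string length distribution alongside the DRL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .motifs import MotifClass, canonical_label, is_primitive, minimal_period

__all__ = [
    "DRL",
    "NormalizedDRL",
    "BHistogram",
    "extract_drl",
    "extract_nonmotif_histogram",
    "normalize_drl",
    "truncate_low_counts",
    "bootstrap_ci",
    "shuffle_control",
    "median_drl",
    "pool_by_unit_length",
]

# Canonical satellite motifs excluded from pooled displays (flagged):
# the centromeric/pericentromeric pentamer (AATGG/CCATT family) and the
# telomeric hexamer (TTAGGG/CCCTAA family), whose DRLs are qualitatively
# unlike those of generic simple repeats.
SATELLITE_LABELS = frozenset({"AATGG", "AACCCT"})


class DegenerateDistributionError(ValueError):
    """Normalization requested over empty support."""


class InsufficientDataError(ValueError):
    """Bootstrap requested with fewer than one full segment."""


@dataclass
class DRL:
    """Integer (or expected, real-valued) counts of tracts per length."""

    motif: MotifClass
    counts: dict
    source: str = ""

    def total(self, L_min: int = 1) -> float:
        return sum(c for L, c in self.counts.items() if L >= L_min)

    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def to_array(self, L_max: int | None = None) -> np.ndarray:
        """Dense counts indexed by length; index 0 is unused (zero)."""
        n = L_max if L_max is not None else self.max_length()
        arr = np.zeros(n + 1)
        for L, c in self.counts.items():
            if 1 <= L <= n:
                arr[L] += c
        return arr

    @classmethod
    def from_array(cls, motif: MotifClass, arr, source: str = "") -> "DRL":
        counts = {L: float(c) for L, c in enumerate(arr) if L >= 1 and c != 0}
        return cls(motif, counts, source)

    def __add__(self, other: "DRL") -> "DRL":
        if self.motif != other.motif:
            raise ValueError("cannot pool DRLs of different motif classes")
        counts = dict(self.counts)
        for L, c in other.counts.items():
            counts[L] = counts.get(L, 0) + c
        return DRL(self.motif, counts, self.source)


@dataclass
class NormalizedDRL:
    """Conditional probability distribution P(L | L >= L_min)."""

    motif: MotifClass
    L_min: int
    probs: dict
    source: str = ""
    reference_total: float = field(default=0.0)

    def to_array(self, L_max: int | None = None) -> np.ndarray:
        n = L_max if L_max is not None else (max(self.probs) if self.probs else 0)
        arr = np.zeros(n + 1)
        for L, p in self.probs.items():
            if 1 <= L <= n:
                arr[L] += p
        return arr

    def rescale_to(self, total: float) -> DRL:
        """Invert normalization against a reference total count."""
        return DRL(self.motif, {L: p * total for L, p in self.probs.items()})


@dataclass
class BHistogram:
    """Counts of contiguous non-motif stretch lengths (nt), per class."""

    motif: MotifClass
    counts: dict

    def to_array(self, L_max: int | None = None) -> np.ndarray:
        n = L_max if L_max is not None else (max(self.counts) if self.counts else 0)
        arr = np.zeros(n + 1)
        for L, c in self.counts.items():
            if 1 <= L <= n:
                arr[L] += c
        return arr


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


def _encode(sequence: str) -> np.ndarray:
    """Uppercase sequence to int8 codes; non-ACGT mapped to -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
        lut[ord(b.lower())] = c
    return lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _chunks(codes: np.ndarray):
    """Yield (offset, sub-array) of maximal runs of valid (non-negative) codes."""
    valid = codes >= 0
    if not valid.any():
        return
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    starts = [0] if valid[0] else []
    starts += [int(e) + 1 for e in edges if valid[e + 1]]
    ends = [int(e) + 1 for e in edges if valid[e]]
    if valid[-1]:
        ends.append(len(codes))
    for s, e in zip(starts, ends):
        yield s, codes[s:e]


def _kmer_class_lookup(k: int):
    """Map base-4 k-mer codes -> (class index, list of classes).

    Non-primitive k-mers map to -1: a degenerate motif such as "AA" is not a
    unit-2 repeat but a disguise of the unit-1 class, and is excluded here.
    """
    classes: list = []
    index: dict = {}
    lut = np.full(4**k, -1, dtype=np.int32)
    for code in range(4**k):
        digits = []
        c = code
        for _ in range(k):
            digits.append(_CODE_BASE[c % 4])
            c //= 4
        kmer = "".join(reversed(digits))
        if not is_primitive(kmer):
            continue
        cls = canonical_label(kmer)
        if cls.label not in index:
            index[cls.label] = len(classes)
            classes.append(cls)
        lut[code] = index[cls.label]
    return lut, classes


def _kmer_codes(chunk: np.ndarray, k: int) -> np.ndarray:
    """Base-4 rolling codes of all k-mers in chunk (length n-k+1)."""
    n = len(chunk)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        codes = codes * 4 + chunk[i : n - k + 1 + i]
    return codes


def _extract_unit_length(chunk: np.ndarray, k: int, add_counts) -> None:
    """Count tracts of every unit-k motif class in one N-free chunk."""
    n = len(chunk)
    if n < k:
        return
    lut, classes = _kmer_class_lookup(k)
    kcodes = _kmer_codes(chunk, k)
    cls_of_pos = lut[kcodes]  # class index of the k-mer starting at each pos
    cover = np.full(n, -1, dtype=np.int32)  # class claiming each position

    if n > k:
        periodic = chunk[:-k] == chunk[k:]
        # maximal runs of periodic positions -> repeated regions
        edges = np.flatnonzero(np.diff(periodic.astype(np.int8)))
        starts = ([0] if periodic[0] else []) + [
            int(e) + 1 for e in edges if periodic[e + 1]
        ]
        ends = [int(e) + 1 for e in edges if periodic[e]] + (
            [len(periodic)] if periodic[-1] else []
        )
        for s, e in zip(starts, ends):
            region_nt = e - s + k
            ci = cls_of_pos[s]
            if ci < 0:  # unit is non-primitive: region belongs to a shorter class
                continue
            add_counts(classes[ci], region_nt // k, 1)
            cover[s : e + k] = ci

    # isolated single units: a member k-mer not overlapping a region of its
    # own class (partial extensions already counted above as L = 1 regions)
    ok = cls_of_pos >= 0
    for shift in range(k):
        ok &= cover[shift : shift + len(cls_of_pos)] != cls_of_pos
    for ci in np.unique(cls_of_pos[ok]):
        add_counts(classes[ci], 1, int(np.sum(cls_of_pos[ok] == ci)))


def extract_drl(sequence: str, unit_lengths=(1,)) -> dict:
    """Extract DRLs for every motif class at the requested unit lengths.

    Any non-ACGT character (N, gaps) terminates all tracts.  Returns a dict
    keyed by :class:`MotifClass`; classes with no tracts are absent.
    """
    unit_lengths = sorted(set(int(k) for k in unit_lengths))
    if any(k < 1 or k > 6 for k in unit_lengths):
        raise ValueError("unit lengths must be within 1-6")
    acc: dict = {}

    def add_counts(cls, L, c):
        d = acc.setdefault(cls, {})
        d[L] = d.get(L, 0) + c

    codes = _encode(sequence)
    for _, chunk in _chunks(codes):
        for k in unit_lengths:
            _extract_unit_length(chunk, k, add_counts)
    return {cls: DRL(cls, counts) for cls, counts in acc.items()}


def extract_nonmotif_histogram(sequence: str, motif: MotifClass) -> BHistogram:
    """Lengths of maximal stretches free of any member of the class.

    Per-member absence histograms are pooled, mirroring the pooling of the
    DRL itself: for class "A" the A-absence and T-absence histograms are
    combined.
    """
    counts: dict = {}
    codes = _encode(sequence)
    k = motif.unit_length
    members_codes = []
    for m in sorted(motif.members):
        code = 0
        for ch in m:
            code = code * 4 + _BASE_CODE[ch]
        members_codes.append(code)

    for _, chunk in _chunks(codes):
        n = len(chunk)
        for mc in members_codes:
            occupied = np.zeros(n, dtype=bool)
            if n >= k:
                kcodes = _kmer_codes(chunk, k)
                hits = np.flatnonzero(kcodes == mc)
                for h in hits:
                    occupied[h : h + k] = True
            free = ~occupied
            if not free.any():
                continue
            edges = np.flatnonzero(np.diff(free.astype(np.int8)))
            starts = ([0] if free[0] else []) + [int(e) + 1 for e in edges if free[e + 1]]
            ends = [int(e) + 1 for e in edges if free[e]] + ([n] if free[-1] else [])
            for s, e in zip(starts, ends):
                counts[e - s] = counts.get(e - s, 0) + 1
    return BHistogram(motif, counts)


# ---------------------------------------------------------------------------
# normalization / truncation / pooling
# ---------------------------------------------------------------------------


def normalize_drl(drl: DRL, L_min: int = 1) -> NormalizedDRL:
    """Conditional distribution P(L | L >= L_min)."""
    total = drl.total(L_min)
    if total <= 0:
        raise DegenerateDistributionError(
            f"no counts at lengths >= {L_min} for class {drl.motif.label}"
        )
    probs = {L: c / total for L, c in drl.counts.items() if L >= L_min and c != 0}
    return NormalizedDRL(drl.motif, L_min, probs, drl.source, reference_total=total)


def truncate_low_counts(drl: DRL, threshold: float = 30) -> DRL:
    """Drop every bin at or above the lowest length with count < threshold.

    Assembly quality limits how deep into the tail counts can be trusted;
    this applies the fixed truncation rule (default: first bin under 30).
    """
    if not drl.counts:
        return replace(drl, counts={})
    cutoff = None
    for L in range(1, drl.max_length() + 1):
        if drl.counts.get(L, 0) < threshold:
            cutoff = L
            break
    if cutoff is None:
        return replace(drl, counts=dict(drl.counts))
    return replace(drl, counts={L: c for L, c in drl.counts.items() if L < cutoff})


def median_drl(ensemble) -> NormalizedDRL:
    """Per-bin median of an ensemble of normalized DRLs.

    Bins missing from a member (beyond its truncation point) enter the
    median as zero.  The result is a per-bin summary and is not guaranteed
    to sum to one.  Even-sized ensembles use the mean of the two central
    values.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    L_max = max((max(m.probs) if m.probs else 0) for m in ensemble)
    mat = np.stack([m.to_array(L_max) for m in ensemble])
    med = np.median(mat, axis=0)
    probs = {L: float(v) for L, v in enumerate(med) if L >= 1 and v > 0}
    first = ensemble[0]
    return NormalizedDRL(first.motif, first.L_min, probs, source="median")


def pool_by_unit_length(drls: dict, exclude_satellites: bool = True) -> dict:
    """Sum DRL counts per unit length (1..6) across motif classes.

    With ``exclude_satellites`` (default), the canonical centromeric
    pentamer and telomeric hexamer classes are left out of the pools.
    """
    pooled: dict = {}
    for cls, drl in drls.items():
        if exclude_satellites and cls.label in SATELLITE_LABELS:
            continue
        d = pooled.setdefault(cls.unit_length, {})
        for L, c in drl.counts.items():
            d[L] = d.get(L, 0) + c
    return pooled


# ---------------------------------------------------------------------------
# resampling controls
# ---------------------------------------------------------------------------


def shuffle_control(sequence: str, seed: int | None = None) -> str:
    """Uniform random permutation of the bases; composition is preserved."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def bootstrap_ci(
    sequence: str,
    unit_lengths=(1,),
    segment_length: int = 1_000_000,
    n_boot: int = 1000,
    seed: int | None = None,
    trim: int | None = None,
) -> dict:
    """Segment-bootstrap confidence intervals for DRL counts.

    The sequence is cut into contiguous non-overlapping segments of
    ``segment_length`` nt (a trailing sub-segment is discarded); segments
    are resampled with replacement to the original number and their DRLs
    summed, ``n_boot`` times.  The per-bin 95% CI is the (min, max) of the
    replicate values after dropping the ``trim`` largest and smallest
    (default 25 of 1000, scaled proportionally for other ``n_boot``).

    Returns {MotifClass: {length: (lo, hi)}}.
    """
    n_seg = len(sequence) // segment_length
    if n_seg < 1:
        raise InsufficientDataError("need at least one full segment")
    if trim is None:
        trim = int(round(25 * n_boot / 1000))
    seg_drls = []
    for i in range(n_seg):
        seg = sequence[i * segment_length : (i + 1) * segment_length]
        seg_drls.append(extract_drl(seg, unit_lengths))
    classes = sorted({c for d in seg_drls for c in d}, key=lambda c: (c.unit_length, c.label))
    L_max = {
        c: max(max(d[c].counts) for d in seg_drls if c in d and d[c].counts)
        for c in classes
    }
    seg_mats = {
        c: np.stack([d[c].to_array(L_max[c]) if c in d else np.zeros(L_max[c] + 1) for d in seg_drls])
        for c in classes
    }
    rng = np.random.default_rng(seed)
    reps = {c: np.empty((n_boot, L_max[c] + 1)) for c in classes}
    for b in range(n_boot):
        idx = rng.integers(0, n_seg, size=n_seg)
        for c in classes:
            reps[c][b] = seg_mats[c][idx].sum(axis=0)
    out: dict = {}
    for c in classes:
        mat = np.sort(reps[c], axis=0)
        kept = mat[trim : n_boot - trim] if trim > 0 else mat
        out[c] = {
            L: (float(kept[:, L].min()), float(kept[:, L].max()))
            for L in range(1, L_max[c] + 1)
        }
    return out
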