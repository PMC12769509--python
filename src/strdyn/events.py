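"""Classification of de novo mutation events at repeat loci and
length-stratified rate estimation.

An indel at a repeat tract is an *expansion* if it inserts whole in-phase
motif units while keeping the tract contiguous, a *contraction* if it
deletes whole units from within the tract, and a *non-motif insertion* if
it inserts non-unit sequence into the interior of a tract (a fission
mechanism).  Everything else is a partial deletion or 'other'.
Classification is alignment-invariant: the tract is measured in the
reference and in the mutated sequence, so left- vs right-aligned VCF
representations of the same physical event classify identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import MotifClass

__all__ = [
    "MutationEvent",
    "Classification",
    "classify_indel_event",
    "classify_substitution",
    "estimate_length_stratified_rates",
    "TARGET_SIZES",
]


@dataclass(frozen=True)
class MutationEvent:
    """One de novo event with enough reference flank to resolve the tract."""

    kind: str  # substitution | insertion | deletion
    ref_flank_left: str
    ref_allele: str
    alt_allele: str
    ref_flank_right: str
    motif: MotifClass

    def ref_sequence(self) -> str:
        return self.ref_flank_left + self.ref_allele + self.ref_flank_right

    def alt_sequence(self) -> str:
        return self.ref_flank_left + self.alt_allele + self.ref_flank_right


@dataclass(frozen=True)
class Classification:
    category: str  # expansion|contraction|non_motif_insertion|partial_deletion|other
    unit_delta: int  # signed change in complete units
    parent_tract_length: int  # units, measured in the reference


def classify_indel_event(ev: MutationEvent) -> Classification:
    """Classify an indel relative to its containing repeat tract.

    The tract is measured around the event locus in the reference and in
    the mutated sequence; whole-unit changes that keep one contiguous
    tract are expansions/contractions, interior non-unit insertions are
    non-motif insertions (fission), and partial-unit deletions are
    partial deletions.
    """
    k = ev.motif.unit_length
    members = ev.motif.members
    pos = len(ev.ref_flank_left)
    ref, alt = ev.ref_sequence(), ev.alt_sequence()

    if ev.kind == "insertion":
        ins = ev.alt_allele
        # reference tract touching the insertion breakpoint
        rs, re_, runits = _best_tract(ref, pos, pos, k, members)
        as_, ae, aunits = _best_tract(alt, pos, pos + len(ins), k, members)
        if runits == 0:
            return Classification("other", 0, 0)
        if (
            len(ins) % k == 0
            and aunits == runits + len(ins) // k
            and (ae - as_) == (re_ - rs) + len(ins)
        ):
            return Classification("expansion", len(ins) // k, runits)
        inside = rs < pos < re_
        if inside:
            return Classification("non_motif_insertion", 0, runits)
        return Classification("other", 0, runits)

    if ev.kind == "deletion":
        dele = ev.ref_allele
        rs, re_, runits = _best_tract(ref, pos, pos + len(dele), k, members)
        if runits == 0:
            return Classification("other", 0, 0)
        within = rs <= pos and pos + len(dele) <= re_
        if not within:
            return Classification("other", 0, runits)
        as_, ae, aunits = _best_tract(alt, pos, pos, k, members)
        if len(dele) % k == 0 and aunits == runits - len(dele) // k:
            return Classification("contraction", -(len(dele) // k), runits)
        return Classification("partial_deletion", 0, runits)

    raise ValueError(f"classify_indel_event expects an indel, got {ev.kind!r}")


def _best_tract(seq: str, span_lo: int, span_hi: int, k: int, members) -> tuple:
    """Largest maximal period-k member tract overlapping [span_lo, span_hi].

    A tract is a maximal region with period k whose unit is a class
    member; 'overlapping' includes abutting the breakpoint for insertions
    (span_lo == span_hi).
    """
    n = len(seq)
    best = (span_lo, span_lo, 0)
    j0 = max(0, span_lo - k)
    j1 = min(n - k, span_hi)
    seen = set()
    for j in range(j0, j1 + 1):
        if j > n - k or seq[j : j + k] not in members:
            continue
        # extend to maximal period-k region containing [j, j+k)
        s = j
        while s - 1 >= 0 and seq[s - 1] == seq[s - 1 + k]:
            s -= 1
        e = j + k
        while e < n and seq[e] == seq[e - k]:
            e += 1
        if (s, e) in seen:
            continue
        seen.add((s, e))
        units = (e - s) // k
        # must actually touch the event span
        if e < span_lo or s > span_hi:
            continue
        if units > best[2]:
            best = (s, e, units)
    return best


def classify_substitution(ev: MutationEvent) -> str:
    """Trinucleotide-context category of a substitution (unit length 1).

    Categories: lengthening (BBA>BAA or ABB>AAB), shortening (AAB>ABB or
    BAA>BBA), fusion (ABA>AAA), fission (AAA>ABA), create_a1 (BBB>BAB),
    destroy_a1 (BAB>BBB), or 'other'.
    """
    if ev.motif.unit_length != 1:
        raise NotImplementedError("context classification is defined for unit length 1")
    if ev.kind != "substitution" or len(ev.ref_allele) != 1 or len(ev.alt_allele) != 1:
        raise ValueError("expects a single-nucleotide substitution")
    # focal letter: the class member actually present locally (A or its
    # reverse complement); pick whichever of the two members is involved
    letters = sorted(ev.motif.members)
    lf = ev.ref_flank_left[-1] if ev.ref_flank_left else "N"
    rt = ev.ref_flank_right[0] if ev.ref_flank_right else "N"
    for a in letters:
        is_a = lambda ch: ch == a  # noqa: E731
        ctx = ("A" if is_a(lf) else "B", "A" if is_a(ev.ref_allele) else "B",
               "A" if is_a(ev.alt_allele) else "B", "A" if is_a(rt) else "B")
        l, r0, r1, r = ctx
        if r0 == r1:
            continue
        if r0 == "B" and r1 == "A":  # gains a unit
            if l == "A" and r == "A":
                return "fusion"
            if l == "B" and r == "B":
                return "create_a1"
            return "lengthening"
        if r0 == "A" and r1 == "B":  # loses a unit
            if l == "A" and r == "A":
                return "fission"
            if l == "B" and r == "B":
                return "destroy_a1"
            return "shortening"
    return "other"


# per-tract target sizes by process (in units of 'targets per tract of
# length L'): expansions/contractions can hit any of the L units, boundary
# substitutions have two targets, interior (fission) substitutions L - 2.
TARGET_SIZES = {
    "expansion": lambda L: L,
    "contraction": lambda L: L,
    "non_motif_insertion": lambda L: L,
    "lengthening": lambda L: 2,
    "shortening": lambda L: 2,
    "fission": lambda L: max(L - 2, 0),
}


def estimate_length_stratified_rates(
    events,
    denominators,
    n_offspring_genomes: int,
    n_rep: int = 200,
    trim: int = 5,
    seed: int | None = None,
    max_length: int | None = None,
):
    """Per-length, per-process mutation rates with Poisson CIs.

    rate(L) = count(L) / denominator(L) / n_offspring_genomes / target(L),
    where ``denominators`` maps length -> number of tracts of that length
    in the target genome and target(L) is the process's per-tract target
    size.  95% CIs come from ``n_rep`` Poisson resamples of the counts,
    dropping the ``trim`` largest and smallest replicate rates per bin
    (190 of 200 retained by default).  Lengths with zero denominator get
    NaN (undefined), never zero.

    ``events`` is an iterable of (category, parent_tract_length) pairs or
    :class:`Classification` objects.  Multi-unit events (|unit_delta| > 1)
    should be excluded upstream if single-unit rates are wanted.

    Returns {category: {"length", "rate", "ci_lo", "ci_hi", "count"}} with
    aligned numpy arrays.
    """
    counts: dict = {}
    for ev in events:
        if isinstance(ev, Classification):
            cat, L = ev.category, ev.parent_tract_length
        else:
            cat, L = ev
        if cat not in TARGET_SIZES:
            continue
        counts.setdefault(cat, {})
        counts[cat][L] = counts[cat].get(L, 0) + 1

    if hasattr(denominators, "counts"):
        denominators = denominators.counts
    rng = np.random.default_rng(seed)
    out: dict = {}
    for cat, per_len in counts.items():
        Ls = np.array(sorted(per_len))
        if max_length is not None:
            Ls = Ls[Ls <= max_length]
        c = np.array([per_len[L] for L in Ls], dtype=float)
        denom = np.array([denominators.get(int(L), 0) for L in Ls], dtype=float)
        tgt = np.array([TARGET_SIZES[cat](int(L)) for L in Ls], dtype=float)
        scale = denom * n_offspring_genomes * tgt
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(scale > 0, c / scale, np.nan)
        reps = rng.poisson(c[None, :].repeat(n_rep, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            rep_rates = np.where(scale[None, :] > 0, reps / scale[None, :], np.nan)
        rep_rates = np.sort(rep_rates, axis=0)
        kept = rep_rates[trim : n_rep - trim] if trim > 0 else rep_rates
        out[cat] = {
            "length": Ls,
            "count": c,
            "rate": rate,
            "ci_lo": kept.min(axis=0),
            "ci_hi": kept.max(axis=0),
        }
    return out
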