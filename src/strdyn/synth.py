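"""Synthetic data generation: random genomes, a sequence-level forward
simulator (the brute-force oracle for the bin kernel), primate-like DRL
ensembles, and labeled de novo mutation events.

The sequence-level simulator applies every mutational process literally to
an explicit two-letter (A/B) genome: fission and fusion emerge from the
sequence itself rather than from bin bookkeeping, which makes it an
independent check of the aggregate kernel's transition rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .drl import DRL
from .events import Classification, MutationEvent
from .kernel import SimState
from .motifs import MotifClass, canonical_label
from .rates import RateCurve, SubstitutionContextRates

__all__ = [
    "SyntheticGenomeSpec",
    "generate_genome",
    "binary_genome",
    "binary_drl",
    "binary_state",
    "sequence_level_simulate",
    "simulate_binary",
    "generate_primate_ensemble",
    "generate_trio_events",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    length: int
    p_a: float = 0.372
    alphabet: str = "two_letter"  # or "four_letter"
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.p_a <= 1:
            raise ValueError("p_a must lie in [0, 1]")
        if self.alphabet not in ("two_letter", "four_letter"):
            raise ValueError("alphabet must be two_letter or four_letter")


def generate_genome(spec: SyntheticGenomeSpec) -> str:
    """I.i.d. random genome; P(A) = p_a, other letters equiprobable."""
    rng = np.random.default_rng(spec.seed)
    if spec.alphabet == "two_letter":
        arr = np.where(rng.random(spec.length) < spec.p_a, ord("A"), ord("B"))
    else:
        p = (1 - spec.p_a) / 3
        arr = rng.choice(
            np.frombuffer(b"ACGT", dtype=np.uint8),
            size=spec.length,
            p=[spec.p_a, p, p, p],
        )
    return arr.astype(np.uint8).tobytes().decode("ascii")


def binary_genome(length: int, p_a: float, seed: int | None = None) -> np.ndarray:
    """Two-letter genome as a uint8 0/1 array (1 = A site)."""
    rng = np.random.default_rng(seed)
    return (rng.random(length) < p_a).astype(np.uint8)


def _runs(arr: np.ndarray):
    """(values, lengths, starts) of maximal runs."""
    n = len(arr)
    if n == 0:
        return (np.empty(0, np.uint8), np.empty(0, np.int64), np.empty(0, np.int64))
    edges = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [n]])
    return arr[starts], ends - starts, starts


def binary_drl(arr: np.ndarray, L_max: int | None = None) -> np.ndarray:
    """Histogram of A-run lengths of a 0/1 genome (index = length)."""
    vals, lens, _ = _runs(arr)
    alens = lens[vals == 1]
    n = L_max if L_max is not None else (alens.max() if len(alens) else 1)
    return np.bincount(np.minimum(alens, n), minlength=n + 1).astype(float)


def binary_b_hist(arr: np.ndarray, L_max: int | None = None) -> np.ndarray:
    vals, lens, _ = _runs(arr)
    blens = lens[vals == 0]
    n = L_max if L_max is not None else (blens.max() if len(blens) else 1)
    return np.bincount(np.minimum(blens, n), minlength=n + 1).astype(float)


def binary_state(arr: np.ndarray, L_bound: int) -> SimState:
    """Kernel state (A and B histograms) counted from a binary genome."""
    return SimState(binary_drl(arr, L_bound), binary_b_hist(arr, L_bound))


class OracleInvalidError(RuntimeError):
    """Per-target probabilities too large for the one-event-per-target regime."""


@njit(cache=True)
def _sim_core(arr, n_gen, sl, ss, sf, sfus, c1, d1, bi, bdel, bd1, eps, kap, iot, seed):
    """Compiled per-generation event loop over an explicit 0/1 genome."""
    np.random.seed(seed)
    LB = len(eps) - 1
    cap = len(arr) * 2 + 4096
    cur = np.zeros(cap, dtype=np.uint8)
    cur[: len(arr)] = arr
    n = len(arr)
    nxt = np.zeros(cap, dtype=np.uint8)
    rstart = np.zeros(cap, dtype=np.int64)
    rlen = np.zeros(cap, dtype=np.int64)
    rval = np.zeros(cap, dtype=np.uint8)
    cums = np.zeros((7, cap), dtype=np.float64)
    EVCAP = 65536
    ev_pos = np.zeros(EVCAP, dtype=np.int64)
    ev_kind = np.zeros(EVCAP, dtype=np.int64)  # 1 ins A, 0 ins B, -1 del
    flips = np.empty(4096, dtype=np.int64)

    for _g in range(n_gen):
        # --- derive runs ---
        m = 0
        i = 0
        while i < n:
            j = i + 1
            v = cur[i]
            while j < n and cur[j] == v:
                j += 1
            rstart[m] = i
            rlen[m] = j - i
            rval[m] = v
            m += 1
            i = j
        nev = 0
        nflip = 0

        # helper-free inline sampling per process ------------------------
        # (1) weighted processes on runs: build all cumulative weights in
        # one pass.  process codes: 0 fission(A), 1 create_a1(B),
        # 2 expansion, 3 contraction, 4 nonmotif-ins, 5 b_insert, 6 b_delete
        t0 = t1 = t2 = t3 = t4 = t5 = t6 = 0.0
        for r in range(m):
            Lr = rlen[r]
            Lc = Lr if Lr < LB else LB
            if rval[r] == 1:
                if Lr >= 3:
                    t0 += sf * (Lr - 2)
                t2 += eps[Lc] * Lr
                if Lr >= 2:
                    t3 += kap[Lc] * Lr
                    t4 += iot[Lc] * Lr
            else:
                if Lr >= 3:
                    t1 += c1 * (Lr - 2)
                    t6 += bdel * Lr
                if Lr >= 2:
                    t5 += bi * Lr
            cums[0, r] = t0
            cums[1, r] = t1
            cums[2, r] = t2
            cums[3, r] = t3
            cums[4, r] = t4
            cums[5, r] = t5
            cums[6, r] = t6
        for proc in range(7):
            tot = cums[proc, m - 1] if m > 0 else 0.0
            if tot <= 0.0:
                continue
            k = np.random.poisson(tot)
            for _e in range(k):
                u = np.random.random() * tot
                lo, hi = 0, m - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if cums[proc, mid] < u:
                        lo = mid + 1
                    else:
                        hi = mid
                r = lo
                Lr = rlen[r]
                s = rstart[r]
                if (proc in (0, 1) and Lr < 3) or (proc in (3, 4) and Lr < 2):
                    continue  # u landed on a zero-weight run (measure zero)
                if proc == 0 and nflip < 4096:
                    flips[nflip] = s + 1 + np.random.randint(0, Lr - 2)
                    nflip += 1
                elif proc == 1 and nflip < 4096:
                    flips[nflip] = s + 1 + np.random.randint(0, Lr - 2)
                    nflip += 1
                elif proc == 2 and nev < EVCAP:
                    ev_pos[nev] = s + np.random.randint(0, Lr + 1)
                    ev_kind[nev] = 1
                    nev += 1
                elif proc == 3 and nev < EVCAP:
                    ev_pos[nev] = s + np.random.randint(0, Lr)
                    ev_kind[nev] = -1
                    nev += 1
                elif proc == 4 and nev < EVCAP:
                    ev_pos[nev] = s + 1 + np.random.randint(0, Lr - 1)
                    ev_kind[nev] = 0
                    nev += 1
                elif proc == 5 and nev < EVCAP:
                    ev_pos[nev] = s + np.random.randint(0, Lr + 1)
                    ev_kind[nev] = 0
                    nev += 1
                elif proc == 6 and nev < EVCAP:
                    ev_pos[nev] = s + np.random.randint(0, Lr)
                    ev_kind[nev] = -1
                    nev += 1

        # (2) uniform-eligibility processes: count eligible runs once
        nb2 = 0  # B runs len >= 2
        na2 = 0  # A runs len >= 2
        nb1 = 0  # B_1 runs
        na1 = 0  # A_1 runs
        for r in range(m):
            if rval[r] == 1:
                if rlen[r] >= 2:
                    na2 += 1
                else:
                    na1 += 1
            else:
                if rlen[r] >= 2:
                    nb2 += 1
                else:
                    nb1 += 1

        def _nth(target_val, min_len, exact1, idx):
            # find idx-th run with given side/length condition
            c = 0
            for r in range(m):
                if rval[r] != target_val:
                    continue
                if exact1:
                    if rlen[r] != 1:
                        continue
                elif rlen[r] < min_len:
                    continue
                if c == idx:
                    return r
                c += 1
            return -1

        # lengthening: B runs len>=2, one of the two end sites
        k = np.random.poisson(2.0 * sl * nb2) if nb2 > 0 else 0
        for _e in range(k):
            r = _nth(0, 2, False, np.random.randint(0, nb2))
            if r >= 0 and nflip < 4096:
                if np.random.random() < 0.5:
                    flips[nflip] = rstart[r]
                else:
                    flips[nflip] = rstart[r] + rlen[r] - 1
                nflip += 1
        # shortening: A runs len>=2, boundary units
        k = np.random.poisson(2.0 * ss * na2) if na2 > 0 else 0
        for _e in range(k):
            r = _nth(1, 2, False, np.random.randint(0, na2))
            if r >= 0 and nflip < 4096:
                if np.random.random() < 0.5:
                    flips[nflip] = rstart[r]
                else:
                    flips[nflip] = rstart[r] + rlen[r] - 1
                nflip += 1
        # fusion: B_1 runs
        k = np.random.poisson(sfus * nb1) if nb1 > 0 else 0
        for _e in range(k):
            r = _nth(0, 1, True, np.random.randint(0, nb1))
            if r >= 0 and nflip < 4096:
                flips[nflip] = rstart[r]
                nflip += 1
        # destroy A_1
        k = np.random.poisson(d1 * na1) if na1 > 0 else 0
        for _e in range(k):
            r = _nth(1, 1, True, np.random.randint(0, na1))
            if r >= 0 and nflip < 4096:
                flips[nflip] = rstart[r]
                nflip += 1
        # delete B_1
        k = np.random.poisson(bd1 * nb1) if nb1 > 0 else 0
        for _e in range(k):
            r = _nth(0, 1, True, np.random.randint(0, nb1))
            if r >= 0 and nev < EVCAP:
                ev_pos[nev] = rstart[r]
                ev_kind[nev] = -1
                nev += 1

        # --- apply flips ---
        for f in range(nflip):
            cur[flips[f]] ^= 1
        # --- apply indels ---
        if nev > 0:
            # insertion sort of events by position (nev is small)
            for i1 in range(1, nev):
                p = ev_pos[i1]
                kd = ev_kind[i1]
                j1 = i1 - 1
                while j1 >= 0 and ev_pos[j1] > p:
                    ev_pos[j1 + 1] = ev_pos[j1]
                    ev_kind[j1 + 1] = ev_kind[j1]
                    j1 -= 1
                ev_pos[j1 + 1] = p
                ev_kind[j1 + 1] = kd
            w = 0
            prev = 0
            for e in range(nev):
                p = ev_pos[e]
                if p < prev:
                    continue  # overlapped a prior deletion
                for x in range(prev, p):
                    nxt[w] = cur[x]
                    w += 1
                if ev_kind[e] == -1:
                    prev = p + 1
                else:
                    if w < cap:
                        nxt[w] = 1 if ev_kind[e] == 1 else 0
                        w += 1
                    prev = p
            for x in range(prev, n):
                nxt[w] = cur[x]
                w += 1
            if w > cap:
                return cur[:0]  # overflow sentinel (never at sane rates)
            cur[:w] = nxt[:w]
            n = w
    return cur[:n].copy()


def simulate_binary(
    arr: np.ndarray,
    subst: SubstitutionContextRates,
    curve: RateCurve,
    generations: int,
    seed: int | None = None,
    check: bool = True,
) -> np.ndarray:
    """Evolve an explicit 0/1 genome for ``generations`` generations.

    Each generation, the genome's runs are re-derived and every process
    draws a Poisson number of events against its literal sequence targets:
    boundary/interior substitutions flip sites, expansions insert an A
    unit into a tract, contractions delete one, non-motif insertions break
    a tract at an interior junction, and B-string indels edit B runs.
    Fusion and fission are emergent: flipping an interrupting B_1 joins
    the two real neighbor tracts.
    """
    arr = np.ascontiguousarray(arr, dtype=np.uint8)
    if check:
        L = np.arange(curve.L_bound + 1)
        tot = (curve.eps + curve.kap + curve.iot) * L + (
            2 * subst.lengthening
            + 2 * subst.shortening
            + subst.fission * np.clip(L - 2, 0, None)
        )
        if tot.max() >= 0.5:
            raise OracleInvalidError(
                "per-tract event probability >= 0.5; oracle assumptions break"
            )
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    out = _sim_core(
        arr,
        int(generations),
        subst.lengthening,
        subst.shortening,
        subst.fission,
        subst.fusion,
        subst.create_a1,
        subst.destroy_a1,
        subst.b_insert,
        subst.b_delete,
        subst.b1_delete,
        curve.eps.astype(np.float64),
        curve.kap.astype(np.float64),
        curve.iot.astype(np.float64),
        int(seed) % (2**31 - 1),
    )
    if len(out) == 0:
        raise OracleInvalidError("event buffer overflow; rates far too high")
    return out


def sequence_level_simulate(
    sequence: str,
    subst: SubstitutionContextRates,
    curve: RateCurve,
    generations: int,
    seed: int | None = None,
) -> str:
    """String-in/string-out wrapper of :func:`simulate_binary` (A/B genome)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8) == ord("A")
    out = simulate_binary(arr.astype(np.uint8), subst, curve, generations, seed)
    return np.where(out == 1, ord("A"), ord("B")).astype(np.uint8).tobytes().decode()


# ---------------------------------------------------------------------------
# primate-like ensembles
# ---------------------------------------------------------------------------


def generate_primate_ensemble(
    base: DRL | np.ndarray,
    n: int = 36,
    dispersion: float = 0.05,
    seed: int | None = None,
    truncate_threshold: float = 30,
    motif: MotifClass | None = None,
) -> list:
    """Perturbed replicates of an equilibrated DRL, standing in for the
    spread of assemblies across a primate-like clade.

    Per-bin counts are gamma-Poisson: count ~ Poisson(c * g) with
    g ~ Gamma(1/dispersion^2, dispersion^2) (mean 1, CV = dispersion),
    emulating assembly-quality variation on top of sampling noise;
    ``dispersion = 0`` returns exact copies.  The low-count truncation
    rule (< ``truncate_threshold``) is applied to each member.
    """
    if motif is None:
        motif = base.motif if isinstance(base, DRL) else canonical_label("A")
    arr = base.to_array() if isinstance(base, DRL) else np.asarray(base, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if dispersion == 0:
            counts = arr.copy()
        else:
            shape = 1.0 / dispersion**2
            g = rng.gamma(shape, 1.0 / shape, size=len(arr))
            counts = rng.poisson(np.clip(arr * g, 0, None)).astype(float)
        drl = DRL.from_array(motif, counts, source=f"synthetic-member-{i}")
        if truncate_threshold:
            from .drl import truncate_low_counts

            drl = truncate_low_counts(drl, truncate_threshold)
        out.append(drl)
    return out


# ---------------------------------------------------------------------------
# labeled mutation events
# ---------------------------------------------------------------------------


def generate_trio_events(
    curve: RateCurve,
    denominators: DRL | np.ndarray,
    n_genomes: int,
    seed: int | None = None,
    motif: MotifClass | None = None,
    flank: int = 6,
    max_events: int | None = None,
):
    """Sample de novo indel events with known truth labels.

    For each process and tract length L the event count is Poisson with
    mean rate(L) * target(L) * denominator(L) * n_genomes; each event is
    rendered as a :class:`MutationEvent` with G/C flanks around an A-run
    and paired with its generating :class:`Classification`.

    Returns (events, truths) lists.
    """
    if motif is None:
        motif = canonical_label("A")
    rng = np.random.default_rng(seed)
    denom = (
        denominators.to_array() if isinstance(denominators, DRL)
        else np.asarray(denominators, dtype=float)
    )
    LB = min(len(denom) - 1, curve.L_bound)
    events, truths = [], []

    def fl():
        return "".join(rng.choice(list("GC"), size=flank))

    for L in range(1, LB + 1):
        d = denom[L]
        if d <= 0:
            continue
        n_exp = rng.poisson(curve.eps[L] * L * d * n_genomes)
        n_con = rng.poisson(curve.kap[L] * L * d * n_genomes) if L >= 2 else 0
        n_ins = rng.poisson(curve.iot[L] * L * d * n_genomes) if L >= 2 else 0
        for _ in range(n_exp):
            j = rng.integers(0, L + 1)
            events.append(
                MutationEvent("insertion", fl() + "A" * j, "", "A", "A" * (L - j) + fl(),
                              motif)
            )
            truths.append(Classification("expansion", 1, L))
        for _ in range(n_con):
            j = rng.integers(0, L)
            events.append(
                MutationEvent("deletion", fl() + "A" * j, "A", "",
                              "A" * (L - 1 - j) + fl(), motif)
            )
            truths.append(Classification("contraction", -1, L))
        for _ in range(n_ins):
            j = rng.integers(1, L)
            events.append(
                MutationEvent("insertion", fl() + "A" * j, "", "G",
                              "A" * (L - j) + fl(), motif)
            )
            truths.append(Classification("non_motif_insertion", 0, L))
        if max_events and len(events) >= max_events:
            break
    return events, truths
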