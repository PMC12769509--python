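"""Table formats, configuration, and the end-to-end pipeline.

All tables are TSV with '#'-prefixed metadata headers; summaries are
JSON; configuration is YAML.  Numeric fields serialize at 17 significant
digits so write -> read round-trips are exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .drl import DRL, NormalizedDRL, extract_drl, normalize_drl
from .motifs import canonical_label
from .rates import (
    ParamGrid,
    ParamSpec,
    RateCurve,
    SubstitutionContextRates,
    build_rate_table,
    default_empirical_curve,
    uniform_prior,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_drl_table",
    "read_drl_table",
    "write_rate_table",
    "read_rate_table",
    "write_subst_yaml",
    "read_subst_yaml",
    "write_trajectory",
    "write_flux_table",
    "write_posterior",
    "read_posterior",
    "PipelineConfig",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"


class TableFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list:
    """[(record id, uppercased sequence), ...].  Softmasked (lowercase)
    bases are uppercased; records are never concatenated."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# DRL tables
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_tsv(path):
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas detail
            raise TableFormatError(f"{path}: {exc}") from exc
    return df, meta


def write_drl_table(drls, path, meta: dict | None = None) -> None:
    """Columns: motif_label, unit_length, tract_length_units, count.

    ``drls`` may be a dict {MotifClass: DRL} or a single DRL; normalized
    DRLs add a ``prob`` column and an L_min metadata header.
    """
    if isinstance(drls, (DRL, NormalizedDRL)):
        drls = {drls.motif: drls}
    rows = []
    normalized = any(isinstance(d, NormalizedDRL) for d in drls.values())
    meta = dict(meta or {})
    for cls, d in sorted(drls.items(), key=lambda x: (x[0].unit_length, x[0].label)):
        if isinstance(d, NormalizedDRL):
            meta["L_min"] = d.L_min
            for L in sorted(d.probs):
                rows.append((cls.label, cls.unit_length, L,
                             d.probs[L] * d.reference_total, d.probs[L]))
        else:
            for L in sorted(d.counts):
                rows.append((cls.label, cls.unit_length, L, d.counts[L], np.nan))
    base = ["motif_label", "unit_length", "tract_length_units", "count"]
    df = pd.DataFrame(rows, columns=base + ["prob"])
    if not normalized:
        df = df[base]
    _write_tsv(df, path, meta)


DRL_COLUMN_MAP = {
    "motif": "motif_label",
    "motif_label": "motif_label",
    "unit": "unit_length",
    "unit_length": "unit_length",
    "length": "tract_length_units",
    "tract_length": "tract_length_units",
    "tract_length_units": "tract_length_units",
    "count": "count",
    "counts": "count",
}


def read_drl_table(path, column_map: dict | None = None) -> dict:
    """Read a DRL table back into {MotifClass: DRL}.

    ``column_map`` renames nonstandard columns (externally published
    table layouts) onto the canonical names before parsing; unknown
    columns after mapping raise.
    """
    df, meta = _read_tsv(path)
    cmap = {**DRL_COLUMN_MAP, **(column_map or {})}
    renamed = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in cmap:
            renamed[col] = cmap[key]
    df = df.rename(columns=renamed)
    required = {"motif_label", "tract_length_units", "count"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: unmapped columns, missing {sorted(missing)}")
    if df["count"].isna().any():
        raise TableFormatError(f"{path}: missing count values")
    out: dict = {}
    for label, sub in df.groupby("motif_label"):
        cls = canonical_label(str(label))
        counts = {
            int(L): float(c)
            for L, c in zip(sub["tract_length_units"], sub["count"])
        }
        out[cls] = DRL(cls, counts, source=str(meta.get("source", path)))
    return out


# ---------------------------------------------------------------------------
# rate tables and substitution rates
# ---------------------------------------------------------------------------

_PROCESSES = ("expansion", "contraction", "non_motif_insertion")


def write_rate_table(curve: RateCurve, path, meta: dict | None = None,
                     cis: dict | None = None) -> None:
    """Columns: process, tract_length_units, rate_per_target_per_generation,
    ci_lo, ci_hi, provenance."""
    rows = []
    arrs = {"expansion": curve.eps, "contraction": curve.kap,
            "non_motif_insertion": curve.iot}
    for proc in _PROCESSES:
        arr = arrs[proc]
        for L in range(1, curve.L_bound + 1):
            lo = hi = np.nan
            if cis and proc in cis:
                lo, hi = cis[proc].get(L, (np.nan, np.nan))
            rows.append((proc, L, arr[L], lo, hi, curve.provenance[L]))
    df = pd.DataFrame(rows, columns=[
        "process", "tract_length_units", "rate_per_target_per_generation",
        "ci_lo", "ci_hi", "provenance",
    ])
    _write_tsv(df, path, meta or {})


RATE_COLUMN_MAP = {
    "process": "process",
    "mutation_type": "process",
    "tract_length_units": "tract_length_units",
    "length": "tract_length_units",
    "tract_length": "tract_length_units",
    "rate": "rate_per_target_per_generation",
    "rate_per_target_per_generation": "rate_per_target_per_generation",
    "ci_lo": "ci_lo",
    "ci_hi": "ci_hi",
    "provenance": "provenance",
}


def read_rate_table(path, column_map: dict | None = None) -> RateCurve:
    """Read a rate table; every process must cover 1..L_bound without
    gaps (a missing length raises, never a silent zero)."""
    df, _ = _read_tsv(path)
    cmap = {**RATE_COLUMN_MAP, **(column_map or {})}
    df = df.rename(columns={c: cmap.get(c.strip().lower(), c) for c in df.columns})
    need = {"process", "tract_length_units", "rate_per_target_per_generation"}
    if need - set(df.columns):
        raise TableFormatError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    L_bound = int(df["tract_length_units"].max())
    arrs = {p: np.zeros(L_bound + 1) for p in _PROCESSES}
    prov = ["parameterized"] * (L_bound + 1)
    for proc in _PROCESSES:
        sub = df[df["process"] == proc]
        got = set(int(v) for v in sub["tract_length_units"])
        expect = set(range(1, L_bound + 1))
        if got != expect:
            raise TableFormatError(
                f"{path}: {proc} has gaps at lengths {sorted(expect - got)[:5]}..."
            )
        for L, r in zip(sub["tract_length_units"], sub["rate_per_target_per_generation"]):
            arrs[proc][int(L)] = float(r)
        if "provenance" in sub.columns:
            for L, p in zip(sub["tract_length_units"], sub["provenance"]):
                prov[int(L)] = str(p)
    return RateCurve(arrs["expansion"], arrs["contraction"],
                     arrs["non_motif_insertion"], prov)


def write_subst_yaml(subst: SubstitutionContextRates, path) -> None:
    data = {f.name: float(getattr(subst, f.name))
            for f in dataclasses.fields(subst)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_subst_yaml(path) -> SubstitutionContextRates:
    data = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(SubstitutionContextRates)}
    unknown = set(data) - fields
    if unknown:
        raise TableFormatError(f"{path}: unknown rate names {sorted(unknown)}")
    return SubstitutionContextRates(**data)


# ---------------------------------------------------------------------------
# trajectories, fluxes, posteriors
# ---------------------------------------------------------------------------


def write_trajectory(traj, path, meta: dict | None = None) -> None:
    rows = []
    for st in traj.states:
        for L in range(1, len(st.a)):
            if st.a[L] != 0 or (L < len(st.b) and st.b[L] != 0):
                b = st.b[L] if L < len(st.b) else 0.0
                rows.append((st.generation, L, st.a[L], b))
    df = pd.DataFrame(rows, columns=["generation", "length", "a_count", "b_count"])
    _write_tsv(df, path, meta or {})


def write_flux_table(flux, path, meta: dict | None = None) -> None:
    rows = []
    for proc, (fin, fout) in flux.processes.items():
        for L in range(1, flux.L_bound + 1):
            if fin[L] != 0 or fout[L] != 0:
                rows.append((proc, L, fin[L], fout[L]))
    df = pd.DataFrame(rows, columns=["process", "length", "influx", "outflux"])
    _write_tsv(df, path, meta or {})


def write_posterior(pg, path, meta: dict | None = None) -> None:
    names = list(pg.grid.axes)
    rows = []
    for spec, pr, kl, po in zip(pg.grid.points(), pg.prior, pg.kl, pg.posterior):
        rows.append(tuple(spec.theta) + (pr, kl, po))
    df = pd.DataFrame(rows, columns=names + ["prior", "kl", "posterior"])
    meta = dict(meta or {})
    meta.setdefault("family", pg.grid.family)
    meta.setdefault("sigma", repr(pg.sigma))
    _write_tsv(df, path, meta)


def read_posterior(path):
    df, meta = _read_tsv(path)
    return df, meta


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run: extract (or synthesize) -> evolve grid -> infer ->
    diagnose.  Scaled-down defaults keep a smoke run at desk scale."""

    out_dir: str = "strdyn_out"
    fasta: str | None = None  # if None, a synthetic genome is generated
    genome_length: float = 1e6
    model_genome_length: float = 3.1e9
    motif: str = "A"
    seed: int = 0
    family: str = "multiplier_coupled_power"
    grid_axes: dict | None = None
    prior: str = "uniform"  # uniform | restrictive | permissive
    ensemble_size: int = 36
    ensemble_dispersion: float = 0.05
    stage_iterations: int = 20000
    total_generations: float = 1e9
    L_min: int = 4
    pseudocount: float = 1.0
    rate_table: str | None = None
    subst_yaml: str | None = None
    log_level: str = "INFO"

    def validate(self):
        for p in (self.fasta, self.rate_table, self.subst_yaml):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data).validate()

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run extract -> evolve -> infer -> diagnose and persist artifacts.

    Returns (and writes as JSON) a report with the posterior summary,
    Bayes factor, HDR occupancies, and steady-state diagnostics for the
    maximum-posterior parameters.  Deterministic under the config seed.
    """
    from . import __version__
    from .inference import (InferenceConfig, bayes_factor, hdr, posterior,
                            primate_sigma, kl_divergence)
    from .kernel import SimConfig, evolve, flux_decomposition, initialize_state
    from .steady import classify_regime
    from .synth import SyntheticGenomeSpec, generate_genome, generate_primate_ensemble

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg.seed)

    # --- stage 1: empirical DRL -------------------------------------------
    if cfg.fasta:
        records = read_fasta(cfg.fasta)
        drls: dict = {}
        for _name, seq in records:
            for cls, d in extract_drl(seq, [len(cfg.motif)]).items():
                drls[cls] = drls[cls] + d if cls in drls else d
        source = cfg.fasta
    else:
        spec = SyntheticGenomeSpec(int(cfg.genome_length), alphabet="four_letter",
                                   p_a=0.31, seed=rng_seed)
        seq = generate_genome(spec)
        drls = extract_drl(seq, [len(cfg.motif)])
        source = f"synthetic(seed={rng_seed})"
    focal = canonical_label(cfg.motif)
    if focal not in drls:
        raise RuntimeError(f"no tracts of class {focal.label} found")
    emp_drl = drls[focal]
    emp_drl.source = source
    write_drl_table(drls, out / "drl.tsv", {"source": source, "seed": rng_seed})

    # --- stage 2: rates and grid ------------------------------------------
    subst = read_subst_yaml(cfg.subst_yaml) if cfg.subst_yaml else (
        SubstitutionContextRates()
    )
    empirical = (read_rate_table(cfg.rate_table) if cfg.rate_table
                 else default_empirical_curve())
    if cfg.grid_axes:
        grid = ParamGrid(cfg.family,
                         {k: np.asarray(v, dtype=float)
                          for k, v in cfg.grid_axes.items()})
    else:
        from .rates import default_grid

        grid = default_grid(cfg.family)
    if cfg.prior == "uniform":
        prior = uniform_prior(grid)
    else:
        raise NotImplementedError(
            "informative priors need a popSTR-style rate table; use the API"
        )

    # --- stage 3: evolve each grid point ----------------------------------
    sim_cfg = SimConfig(stage_iterations=cfg.stage_iterations,
                        total_generations=cfg.total_generations)
    init = initialize_state(cfg.model_genome_length, subst)
    icfg = InferenceConfig(L_min=cfg.L_min, pseudocount=cfg.pseudocount)
    kls = np.empty(grid.n)
    finals = []
    for i, spec_pt in enumerate(grid.points()):
        curve = build_rate_table(spec_pt, empirical, 200, subst)
        traj = evolve(init, subst, curve, sim_cfg)
        finals.append(traj)
        # compare at matched scale: model counts rescaled to empirical total
        model = normalize_drl(DRL(focal, traj.final.drl_counts()), cfg.L_min)
        model_counts = model.rescale_to(emp_drl.total(cfg.L_min)).to_array(200)
        kls[i] = kl_divergence(model_counts, emp_drl, icfg)

    # --- stage 4: sigma from a synthetic ensemble and the posterior --------
    ensemble = generate_primate_ensemble(
        emp_drl, n=cfg.ensemble_size, dispersion=cfg.ensemble_dispersion,
        seed=rng_seed + 1,
    )
    sigma = primate_sigma(ensemble, emp_drl, icfg)
    pg = posterior(kls, prior, sigma, grid)
    write_posterior(pg, out / "posterior.tsv", {"seed": rng_seed})
    best = pg.max_posterior()
    best_i = grid.index_of(best.theta)
    regions = hdr(pg.posterior)

    # --- stage 5: diagnostics at the max posterior -------------------------
    best_curve = build_rate_table(best, empirical, 200, subst)
    best_traj = finals[best_i]
    flux = flux_decomposition(best_traj.final, subst, best_curve)
    write_flux_table(flux, out / "flux.tsv", {"theta": best.theta})
    diag = classify_regime(best, best_traj.final.a, empirical, subst)

    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": rng_seed,
        "family": cfg.family,
        "grid_shape": list(grid.shape),
        "sigma": sigma,
        "max_posterior": list(best.theta),
        "mean_posterior": [float(v) for v in pg.mean_posterior()],
        "bayes_factor": bayes_factor(kls, prior, sigma),
        "hdr_cells": {str(k): int(v.sum()) for k, v in regions.items()},
        "delta_tau": diag.delta_tau,
        "regime": diag.regime,
        "L_star": diag.L_star,
        "L_trunc": diag.L_trunc,
        "equilibrated": bool(best_traj.equilibrated),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
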