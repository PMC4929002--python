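"""End-to-end orchestration: simulate -> call -> infer-ne -> mu -> quantgen
-> selection, with a validated config, per-stage seeds derived from one
master seed, and a manifest of digests and wall times.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, drift, io, quantgen, simulate

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "summarize_run"]

_SCHEMA: dict[str, dict[str, type]] = {
    "": {"schema_version": int, "seed": int},
    "genome": {"length": int, "gc": float, "x_fraction": float},
    "ma": {"n_lines": int, "t": int, "two_ne": int, "two_ne_x": int, "mu": float,
           "indel_fraction": float},
    "sequencing": {"mean_depth": float, "depth_min": int, "depth_max": int,
                   "error_rate": float, "n_background": int},
    "calling": {"freq_cutoff": float, "leak_freq": float, "max_leak_lines": int,
                "strand_p": float},
    "inference": {"grid_min": int, "grid_max": int, "reps": int, "sample_n": int},
    "traits": {"reps_per_line": int, "pool_n": int, "vm": float, "v_within_ma": float,
               "dgrp_n_lines": int, "vg": float, "v_within_dgrp": float},
    "selection": {"pi": float, "vs_multiplier": float},
}

_DEFAULTS: dict = {
    "schema_version": 1,
    "seed": 1,
    "genome": {"length": 1_000_000, "gc": 0.4248, "x_fraction": 0.2},
    "ma": {"n_lines": 23, "t": 60, "two_ne": 23, "two_ne_x": 19, "mu": 1e-8,
           "indel_fraction": 0.1},
    "sequencing": {"mean_depth": 30.0, "depth_min": 1, "depth_max": 250,
                   "error_rate": 0.001, "n_background": 2000},
    "calling": {"freq_cutoff": 0.2, "leak_freq": 0.05, "max_leak_lines": 2,
                "strand_p": 0.001},
    "inference": {"grid_min": 10, "grid_max": 40, "reps": 20_000, "sample_n": 200},
    "traits": {"reps_per_line": 2, "pool_n": 10, "vm": 2.5e-4, "v_within_ma": 1.0,
               "dgrp_n_lines": 40, "vg": 1.0, "v_within_dgrp": 1.0},
    "selection": {"pi": 4.92e-3, "vs_multiplier": 20.0},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are errors."""

    params: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        params = json.loads(json.dumps(_DEFAULTS))  # deep copy
        for key, value in raw.items():
            if key in _SCHEMA[""]:
                params[key] = _coerce("", key, value)
            elif key in _SCHEMA and isinstance(value, dict):
                for sub, sval in value.items():
                    if sub not in _SCHEMA[key]:
                        raise ValueError(f"unknown config key: {key}.{sub}")
                    params[key][sub] = _coerce(key, sub, sval)
            else:
                raise ValueError(f"unknown config key: {key}")
        cfg = cls(params=params)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        p = self.params
        checks = [
            (p["genome"]["length"] > 0, "genome.length must be positive"),
            (0 < p["genome"]["gc"] < 1, "genome.gc must be in (0, 1)"),
            (p["ma"]["t"] >= 1, "ma.t must be >= 1"),
            (p["ma"]["n_lines"] >= 2, "ma.n_lines must be >= 2"),
            (p["ma"]["two_ne"] >= 2, "ma.two_ne must be >= 2"),
            (p["ma"]["mu"] >= 0, "ma.mu must be non-negative"),
            (p["sequencing"]["depth_min"] <= p["sequencing"]["depth_max"],
             "sequencing depth bounds inverted"),
            (p["inference"]["grid_min"] <= p["inference"]["grid_max"],
             "inference grid inverted"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params, sort_keys=True).encode()
        ).hexdigest()

    def stage_seed(self, stage: int) -> int:
        return int(
            np.random.SeedSequence([self.params["seed"], stage]).generate_state(1)[0]
            % (2**31)
        )


def _coerce(section: str, key: str, value):
    typ = _SCHEMA[section][key]
    if typ is float and isinstance(value, (int, float)):
        return float(value)
    if typ is int and isinstance(value, int):
        return int(value)
    if not isinstance(value, typ):
        where = f"{section}.{key}" if section else key
        raise ValueError(f"config field {where} must be {typ.__name__}")
    return value


@dataclass
class RunManifest:
    """Per-stage output digests, wall times, and the effective config."""

    config: dict
    config_digest: str
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "config_digest": self.config_digest, "stages": self.stages},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(config=d["config"], config_digest=d["config_digest"], stages=d["stages"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _atomic(path: Path, write_fn) -> None:
    tmp = path.with_suffix(path.suffix + ".part")
    write_fn(tmp)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig, outdir: str | Path, force: bool = False) -> RunManifest:
    """Execute all stages, writing outputs and a manifest under ``outdir``.

    Re-running a completed directory with an unchanged config is a no-op
    unless ``force``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        existing = RunManifest.from_json(manifest_path.read_text())
        if existing.config_digest == config.digest():
            return existing
    manifest = RunManifest(config=config.params, config_digest=config.digest())
    p = config.params

    def record(stage: str, started: float, outputs: list[Path], extra: dict | None = None) -> None:
        manifest.stages[stage] = {
            "elapsed_s": round(time.perf_counter() - started, 3),
            "outputs": {o.name: _sha256(o) for o in outputs},
            **(extra or {}),
        }

    # --- stage 1: simulate -------------------------------------------------
    t0 = time.perf_counter()
    g = p["genome"]
    genome = simulate.generate_genome(
        g["length"], gc=g["gc"], x_fraction=g["x_fraction"], seed=config.stage_seed(10)
    )
    ma = p["ma"]
    truth = simulate.simulate_ma_lines(
        genome, ma["n_lines"], ma["t"], ma["mu"], ma["two_ne"],
        seed=config.stage_seed(11), two_ne_x=ma["two_ne_x"],
        indel_fraction=ma["indel_fraction"],
    )
    seqp = p["sequencing"]
    pileups = simulate.render_pileups(
        genome, truth, mean_depth=seqp["mean_depth"],
        depth_bounds=(seqp["depth_min"], seqp["depth_max"]),
        error_rate=seqp["error_rate"], seed=config.stage_seed(12), t=ma["t"],
        n_background=seqp["n_background"],
    )
    tr = p["traits"]
    k_true = quantgen.k_factor(ma["t"], round((ma["two_ne"] + ma["two_ne_x"]) / 2))
    panel_ma = simulate.simulate_trait_panel(
        ma["n_lines"], tr["reps_per_line"], v_line=tr["vm"] * k_true,
        v_within=tr["v_within_ma"], pool_n=tr["pool_n"],
        seed=config.stage_seed(13), trait="demo", sex="F", line_prefix="MA",
    )
    panel_dgrp = simulate.simulate_trait_panel(
        tr["dgrp_n_lines"], tr["reps_per_line"], v_line=tr["vg"],
        v_within=tr["v_within_dgrp"], seed=config.stage_seed(14),
        trait="demo", sex="F", line_prefix="DGRP",
    )
    dgrp_freqs = np.full(200, 0.5)
    _, dgrp_dosage = simulate.simulate_inbred_panel(
        tr["dgrp_n_lines"], dgrp_freqs.size, dgrp_freqs, effect_var=tr["vg"] / dgrp_freqs.size,
        v_within=tr["v_within_dgrp"], seed=config.stage_seed(15),
    )
    files = {
        "genome.fa": lambda q: io.write_genome_fasta(genome, q),
        "truth.vcf": lambda q: io.write_true_mutations_vcf(truth, genome, q, t=ma["t"]),
        "pileups.tsv": lambda q: io.write_pileups_tsv(pileups, q),
        "traits_ma.tsv": lambda q: io.write_trait_panel_tsv(panel_ma, q),
        "traits_dgrp.tsv": lambda q: io.write_trait_panel_tsv(panel_dgrp, q),
        "dgrp_dosage.tsv": lambda q: dgrp_dosage.to_csv(q, sep="\t"),
    }
    for name, fn in files.items():
        _atomic(outdir / name, fn)
    record("simulate", t0, [outdir / n for n in files])

    # --- stage 2: call -----------------------------------------------------
    t0 = time.perf_counter()
    cal = p["calling"]
    sites = calling.eligible_sites(pileups)
    calls = calling.call_mutations(
        pileups, freq_cutoff=cal["freq_cutoff"], leak_freq=cal["leak_freq"],
        max_leak_lines=cal["max_leak_lines"], strand_p=cal["strand_p"], sites=sites,
    )
    summary = calling.summarize_spectrum(calls, genome_gc=genome.gc_fraction)
    _atomic(outdir / "calls.vcf", lambda q: io.write_calls_vcf(calls, genome, q))
    srow = {
        **{f"n_{c.lower()}": n for c, n in summary.class_counts.items()},
        "ti": summary.ti, "tv": summary.tv, "titv_normalized": summary.titv_normalized,
        "n_gc": summary.n_gc, "n_at": summary.n_at, "gc_fold_bias": summary.gc_fold_bias,
    }
    _atomic(outdir / "spectrum.tsv", lambda q: pd.DataFrame([srow]).to_csv(q, sep="\t", index=False))
    record("call", t0, [outdir / "calls.vcf", outdir / "spectrum.tsv"],
           {"n_eligible_sites": len(sites), "n_calls": len(calls)})

    # --- stage 3: infer-ne per chromosome class ----------------------------
    t0 = time.perf_counter()
    inf = p["inference"]
    grid = range(inf["grid_min"], inf["grid_max"] + 1)
    fits: dict[str, drift.NeFit] = {}
    fit_files = []
    for chrom_class in ("A", "X"):
        freqs = [c.frequency for c in calls if c.chrom == chrom_class]
        if len(freqs) < 5:
            continue
        spectrum = drift.bin_spectrum(freqs)
        fit = drift.estimate_ne(
            spectrum, grid=grid, t=ma["t"], reps=inf["reps"],
            sample_n=inf["sample_n"], cutoff=cal["freq_cutoff"],
            seed=config.stage_seed(30),
        )
        fits[chrom_class] = fit
        path = outdir / f"nefit_{chrom_class}.json"
        _atomic(path, lambda q, fit=fit: io.write_nefit_json(fit, q))
        fit_files.append(path)
    if not fits:
        raise RuntimeError("infer-ne: too few calls on every chromosome class")
    record("infer_ne", t0, fit_files,
           {c: {"ml_two_ne": f.ml_two_ne, "p_detect": f.p_detect} for c, f in fits.items()})

    # --- stage 4: mutation rate per line -----------------------------------
    t0 = time.perf_counter()
    depth = pileups.data.groupby(["chrom", "pos", "line_id"])["count"].sum().reset_index()
    site_class = depth[["chrom", "pos"]].drop_duplicates()
    eligible = set(sites)
    rows = []
    class_len = {"X": genome.x_length, "A": len(genome) - genome.x_length}
    for line_id in pileups.ma_line_ids:
        sub = depth[depth["line_id"] == line_id]
        for chrom_class in ("A", "X"):
            fit = fits.get(chrom_class) or fits.get("A") or next(iter(fits.values()))
            csub = sub[sub["chrom"] == chrom_class]
            n_sites = len(site_class[site_class["chrom"] == chrom_class])
            if n_sites == 0 or class_len[chrom_class] == 0:
                continue
            ok = csub[(csub["count"] >= 15) & (csub["count"] <= 250)]
            ok = ok[[tuple(x) in eligible for x in ok[["chrom", "pos"]].to_numpy()]]
            frac = len(ok) / n_sites
            b_line = frac * class_len[chrom_class]
            m = sum(1 for c in calls if c.line_id == line_id and c.chrom == chrom_class)
            if b_line <= 0:
                continue
            est = drift.estimate_mutation_rate(
                m, ma["t"], fit.ml_two_ne, fit.p_detect, b_line, line_id=line_id
            )
            rows.append((line_id, chrom_class, m, est.two_ne, est.p, b_line, est.mu))
    rates = pd.DataFrame(
        rows, columns=["line_id", "chrom_class", "m", "two_ne", "p", "callable_bases", "mu"]
    )
    # pooled estimator: robust when per-line counts are small
    denom = (ma["t"] * rates["two_ne"] * rates["p"] * rates["callable_bases"]).sum()
    pooled_mu = float(rates["m"].sum() / denom) if denom > 0 else 0.0
    _atomic(outdir / "rates.tsv", lambda q: rates.to_csv(q, sep="\t", index=False))
    record("mu", t0, [outdir / "rates.tsv"],
           {"median_mu": float(rates["mu"].median()), "pooled_mu": pooled_mu})

    # --- stage 5: quantgen -------------------------------------------------
    t0 = time.perf_counter()
    two_ne_fit = round(float(np.mean([f.ml_two_ne for f in fits.values()])))
    vc_ma = quantgen.partition_variance(panel_ma)
    vc_dgrp = quantgen.partition_variance(panel_dgrp)
    params = quantgen.mutational_heritability(
        vc_ma, t=ma["t"], two_ne=two_ne_fit, pool_n=tr["pool_n"], mode="expression"
    )
    vc_rows = []
    for vc, origin in ((vc_ma, "MA"), (vc_dgrp, "DGRP")):
        vc_rows.append({
            "panel": origin, "trait": vc.trait, "sex": vc.sex, "v_line": vc.v_line,
            "v_within": vc.v_within, "n_lines": vc.n_lines, "p_value": vc.p_value,
        })
    vc_df = pd.DataFrame(vc_rows)
    vc_df["q_value"] = quantgen.fdr_adjust(vc_df["p_value"])
    _atomic(outdir / "varcomp.tsv", lambda q: vc_df.to_csv(q, sep="\t", index=False))
    record("quantgen", t0, [outdir / "varcomp.tsv"],
           {"h2m": params.h2m, "vm": params.vm, "k": params.k})

    # --- stage 6: selection ------------------------------------------------
    t0 = time.perf_counter()
    sel = p["selection"]
    rate_mu = pooled_mu if pooled_mu > 0 else ma["mu"]
    n_pop = quantgen.neutral_population_size(sel["pi"], rate_mu)
    fit_ref = fits.get("A") or next(iter(fits.values()))
    dist = drift.detection_distribution(
        fit_ref.ml_two_ne, t=ma["t"], reps=inf["reps"], sample_n=inf["sample_n"],
        cutoff=cal["freq_cutoff"], seed=config.stage_seed(60),
    )
    dosage_ma = quantgen.ma_dosage_matrix(calls, pileups.ma_line_ids)
    n_below = int(round(len(calls) * dist.p_below / max(dist.p_detect, 1e-12)))
    k = quantgen.k_factor(ma["t"], two_ne_fit)
    sum_var_m_k = quantgen.sequence_variance_sum(
        dosage_ma, k=k, below_cutoff_sampler=dist.sample_below_cutoff,
        n_below=n_below, seed=config.stage_seed(61),
    )
    sum_var_g = quantgen.sequence_variance_sum(dgrp_dosage)
    vg_hat = max(vc_dgrp.v_line, 1e-12)
    report = quantgen.selection_report(
        vm=max(params.vm, 1e-18), vg=vg_hat, sum_var_m_over_k=max(sum_var_m_k, 1e-18),
        sum_var_g=max(sum_var_g, 1e-18), n_pop=n_pop, mu=rate_mu,
        vs_multiplier=sel["vs_multiplier"], ve=params.ve,
    )
    sel_df = pd.DataFrame([{
        "vg": report.vg, "vm_vg": report.vm_vg,
        "neutral_expectation": report.neutral_expectation,
        "sequence_ratio": report.sequence_ratio,
        "effect_size_ratio": report.effect_size_ratio,
        "s_pleiotropic": report.s_pleiotropic, "hoc_n_loci": report.hoc_n_loci,
        "n_pop": n_pop, "mu": rate_mu,
    }])
    _atomic(outdir / "selection.tsv", lambda q: sel_df.to_csv(q, sep="\t", index=False))
    record("selection", t0, [outdir / "selection.tsv"])

    _atomic(manifest_path, lambda q: Path(q).write_text(manifest.to_json()))
    return manifest


def summarize_run(run_dir: str | Path, truth_overlay: bool = False) -> str:
    """Human-readable report of a completed (or partial) run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    lines: list[str] = []
    warn: list[str] = []
    if manifest_path.exists():
        manifest = RunManifest.from_json(manifest_path.read_text())
        lines.append(f"run config digest: {manifest.config_digest[:12]}")
        for stage, meta in manifest.stages.items():
            lines.append(f"stage {stage}: {meta['elapsed_s']} s")
    else:
        warn.append("manifest.json missing; reporting from files present")

    rates_path = run_dir / "rates.tsv"
    if rates_path.exists():
        rates = pd.read_csv(rates_path, sep="\t")
        lines.append("\nper-line mutation rate estimates (mu):")
        lines.append(rates.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    else:
        warn.append("rates.tsv missing")

    for chrom_class in ("A", "X"):
        path = run_dir / f"nefit_{chrom_class}.json"
        if path.exists():
            fit = io.read_nefit_json(path)
            lines.append(
                f"\nML 2Ne ({chrom_class}): {fit.ml_two_ne}  p_detect={fit.p_detect:.4f}"
            )

    spath = run_dir / "spectrum.tsv"
    if spath.exists():
        spec = pd.read_csv(spath, sep="\t")
        if int(spec[[c for c in spec.columns if c.startswith('n_')]].sum(axis=1).iloc[0]) == 0:
            warn.append("empty mutation spectrum: zero calls")
        lines.append("\nmutation spectrum summary:")
        lines.append(spec.to_string(index=False))
    else:
        warn.append("spectrum.tsv missing")

    vpath = run_dir / "varcomp.tsv"
    if vpath.exists():
        lines.append("\nvariance components (h2m inputs):")
        lines.append(pd.read_csv(vpath, sep="\t").to_string(index=False))
    selpath = run_dir / "selection.tsv"
    if selpath.exists():
        sel = pd.read_csv(selpath, sep="\t")
        lines.append("\nselection summary (Vm/Vg vs 1/(4N)):")
        lines.append(sel.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    if truth_overlay and (run_dir / "truth.vcf").exists() and manifest_path.exists():
        manifest = RunManifest.from_json(manifest_path.read_text())
        truth = io.read_true_mutations_vcf(run_dir / "truth.vcf")
        cfg = manifest.config
        lines.append("\nground truth overlay:")
        lines.append(f"  true mu: {cfg['ma']['mu']:.3g}  true 2Ne (A): {cfg['ma']['two_ne']}")
        lines.append(f"  simulated mutations (incl. lost): {len(truth)}")
    if warn:
        lines.append("\nwarnings:")
        lines.extend(f"  - {w}" for w in warn)
    return "\n".join(lines)
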