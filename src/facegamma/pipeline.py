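"""End-to-end orchestration: simulate -> preprocess -> ERP / time-frequency
-> cluster statistics / coupling -> group statistics.

All stage parameters live in one :class:`RunConfig` whose defaults are the
analysis constants used throughout (0.5-20 Hz ERP band, 2.5 x SD rejection,
40 log frequencies 1-200 Hz, 1100-ms dB baseline, 45-150 Hz gamma band with
per-region windows, 3000 permutations at voxel p = 0.05, 3-20 Hz x
45-200 Hz coupling grids with 750-ms windows and z >= 2).  A master seed is
expanded into independent per-stage seeds through fixed spawn keys, so
toggling one stage never shifts another stage's random draws and a re-run
with the same config is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_stats, coupling, erp, group_stats, io_preprocess, timefreq
from .simulate import (FACE_CATEGORIES, CouplingSpec, ErpComponent,
                       GammaBurst, SimConfig, generate_study)

__all__ = ["RunConfig", "run_pipeline"]

_STAGE_KEYS = {"simulate": 0, "preprocess": 1, "erp": 2, "tfr": 3,
               "cluster": 4, "coupling": 5, "stats": 6}
ALL_STAGES = ("simulate", "preprocess", "erp", "tfr", "cluster", "coupling",
              "stats")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    stages: tuple = ALL_STAGES
    erp_band_hz: tuple = (0.5, 20.0)
    rejection_sd_factor: float = 2.5
    n_freqs: int = 40
    freq_range_hz: tuple = (1.0, 200.0)
    tfr_decim: int = 16
    gamma_band_hz: tuple = (45.0, 150.0)
    n_perm: int = 3000
    voxel_p: float = 0.05
    coupling_pairs: tuple = (("fusiform", "amygdala"),
                            ("parahippocampal", "hippocampus"),
                            ("amygdala", "hippocampus"))
    n_surrogates: int = 200

    @classmethod
    def demo(cls, seed: int = 0) -> "RunConfig":
        """Small configuration that runs the full pipeline in minutes."""
        sim = SimConfig(n_patients_per_group=3, n_per_category=6, seed=seed)
        return cls(sim=sim, seed=seed, n_perm=200, n_surrogates=60,
                   coupling_pairs=(("fusiform", "amygdala"),
                                   ("parahippocampal", "hippocampus")))

    # -- lossless serialization ------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim"))
        sim["erp_components"] = tuple(
            ErpComponent(**_tupled(c)) for c in sim.pop("erp_components"))
        sim["gamma_effects"] = tuple(
            GammaBurst(**_tupled(c)) for c in sim.pop("gamma_effects"))
        sim["coupling_specs"] = tuple(
            CouplingSpec(**_tupled(c)) for c in sim.pop("coupling_specs"))
        for k in ("regions", "contact_gains", "isi_range_ms"):
            sim[k] = tuple(sim[k])
        cfg = cls(sim=SimConfig(**sim), **{k: _tupled_v(k, v)
                                           for k, v in d.items()})
        return cfg

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _tupled_v(key, v):
    if key == "coupling_pairs":
        return tuple(tuple(p) for p in v)
    return tuple(v) if isinstance(v, list) else v


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=master,
                                spawn_key=(100 + _STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _log(out_dir: Path, msg: str) -> None:
    print(f"[facegamma] {msg}")
    with open(out_dir / "pipeline.log", "a") as fh:
        fh.write(msg + "\n")


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Run the configured stages; returns the run directory.

    Stage outputs: EDF/TSV inputs under ``input/``, trial tables, cluster
    tables, coupling maps (npz + JSON sidecars), model TSVs and a
    ``manifest.json`` with seeds, parameter hash and per-stage counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    manifest = {
        "seed": cfg.seed,
        "parameter_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": _versions(),
        "stages": {},
    }
    cfg.to_yaml(out_dir / "config.yaml")

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, out_dir, state, manifest)
            _log(out_dir, f"stage {stage} done")
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out_dir


def _versions() -> dict:
    import mne
    import scipy
    import statsmodels

    from . import __version__
    return {"facegamma": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__, "mne": mne.__version__}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, out_dir, state, manifest):
    sim = replace(cfg.sim, seed=_stage_seed(cfg.seed, "simulate"))
    in_dir = out_dir / "input"
    patients = generate_study(sim, in_dir)
    state["in_dir"] = in_dir
    state["patients"] = sorted(patients)
    manifest["stages"]["simulate"] = {
        "n_patients": len(patients),
        "events_per_patient": {p: len(ev) for p, (_, ev) in patients.items()},
    }


def _stage_preprocess(cfg, out_dir, state, manifest):
    in_dir = state["in_dir"]
    counts = {}
    state["erp_epochs"] = {}
    state["gamma_epochs"] = {}
    for pid in state["patients"]:
        rec, events = io_preprocess.read_recording(
            in_dir / f"{pid}.edf", in_dir / "channels.tsv",
            in_dir / f"{pid}_events.tsv", patient=pid)
        rec = io_preprocess.resample_to_1024(rec)

        mono = io_preprocess.rereference(rec, "fz_monopolar")
        ep_m = io_preprocess.epoch(mono, events, reference="fz_monopolar")
        ep_m = io_preprocess.reject_outlier_epochs(ep_m, cfg.rejection_sd_factor)
        ep_m = io_preprocess.bandpass_erp(ep_m, *cfg.erp_band_hz)

        bip = io_preprocess.rereference(rec, "bipolar")
        ep_b = io_preprocess.epoch(bip, events, reference="bipolar")
        ep_b = io_preprocess.reject_outlier_epochs(ep_b, cfg.rejection_sd_factor)

        state["erp_epochs"][pid] = ep_m
        state["gamma_epochs"][pid] = ep_b
        counts[pid] = {
            "trials": int(ep_m.n_trials),
            "erp_rejected": int((~ep_m.kept_mask).sum()),
            "gamma_rejected": int((~ep_b.kept_mask).sum()),
        }
    manifest["stages"]["preprocess"] = counts


def _stage_erp(cfg, out_dir, state, manifest):
    rows = [erp.trial_peak_amplitudes(ep) for ep in state["erp_epochs"].values()]
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out_dir / "erp_trials.tsv", sep="\t", index=False)
    state["erp_rows"] = table
    manifest["stages"]["erp"] = {"n_rows": int(len(table))}


def _stage_tfr(cfg, out_dir, state, manifest):
    freqs = timefreq.log_freqs(cfg.n_freqs, *cfg.freq_range_hz)
    gamma_rows = []
    subject_maps = {}  # region -> list of (patient, group, map)
    for pid, ep in state["gamma_epochs"].items():
        ep_res = timefreq.subtract_erp(ep)
        tf = timefreq.morlet_power(ep_res, freqs, decim=cfg.tfr_decim)
        db = timefreq.baseline_db(tf)
        gamma_rows.append(timefreq.window_gamma_power(db, cfg.gamma_band_hz))
        face_db = timefreq.baseline_db(
            timefreq.average_trials(tf, FACE_CATEGORIES))
        mosaic_db = timefreq.baseline_db(timefreq.average_trials(tf, "mosaic"))
        diff = face_db.power[0] - mosaic_db.power[0]  # channels x f x t
        for ci, ch in enumerate(tf.channels):
            subject_maps.setdefault(ch.region, []).append(
                (pid, ch.group, diff[ci]))
        state.setdefault("tf_axes", (face_db.freqs, face_db.t))
    table = pd.concat(gamma_rows, ignore_index=True)
    table.to_csv(out_dir / "gamma_trials.tsv", sep="\t", index=False)
    state["gamma_rows"] = table
    state["subject_maps"] = {
        r: [(p, g, np.mean([m for pp, gg, m in maps
                            if pp == p and gg == g], axis=0))
            for (p, g) in sorted({(pp, gg) for pp, gg, _ in maps})]
        for r, maps in subject_maps.items()}
    manifest["stages"]["tfr"] = {"n_rows": int(len(table))}


def _stage_cluster(cfg, out_dir, state, manifest):
    rng = np.random.default_rng(_stage_seed(cfg.seed, "cluster"))
    freqs, times = state["tf_axes"]
    summary = {}
    rows = []
    for region, maps in state["subject_maps"].items():
        o = np.stack([m for _, g, m in maps if g == "O"]) if any(
            g == "O" for _, g, _ in maps) else np.empty((0,))
        m_ = np.stack([m for _, g, m in maps if g == "M"]) if any(
            g == "M" for _, g, _ in maps) else np.empty((0,))
        if o.ndim < 3 or m_.ndim < 3 or o.shape[0] < 2 or m_.shape[0] < 2:
            warnings.warn(f"region {region}: fewer than 2 maps per group; "
                          "cluster test skipped")
            continue
        res = cluster_stats.cluster_permutation(
            o, m_, n_perm=cfg.n_perm, voxel_p=cfg.voxel_p, rng=rng)
        summary[region] = {"n_surviving": len(res.clusters),
                           "thr_hi": res.thr_hi, "thr_lo": res.thr_lo,
                           "voxel_threshold": res.voxel_threshold}
        for k, cl in enumerate(res.clusters):
            rows.append((region, k, cl.sign, cl.t_sum, cl.n_pixels,
                         freqs[cl.freq_idx[0]], freqs[cl.freq_idx[1]],
                         times[cl.time_idx[0]], times[cl.time_idx[1]]))
        np.savez(out_dir / f"cluster_{region}.npz", tmap=res.tmap,
                 surviving_mask=res.surviving_mask, null_max=res.null_max,
                 null_min=res.null_min)
    pd.DataFrame(rows, columns=["region", "cluster", "sign", "t_sum",
                                "n_pixels", "f_lo_hz", "f_hi_hz", "t_lo_s",
                                "t_hi_s"]).to_csv(
        out_dir / "clusters.tsv", sep="\t", index=False)
    with open(out_dir / "cluster_thresholds.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["stages"]["cluster"] = summary


def _stage_coupling(cfg, out_dir, state, manifest):
    rng = np.random.default_rng(_stage_seed(cfg.seed, "coupling"))
    results = []
    n_sig = 0
    for pid, ep in state["gamma_epochs"].items():
        present = {c.region for c in ep.channels}
        for phase_region, amp_region in cfg.coupling_pairs:
            if phase_region not in present or amp_region not in present:
                continue
            ch_p = coupling.choose_channel(ep, phase_region)
            ch_a = coupling.choose_channel(ep, amp_region)
            for cond, cats in (("faces", FACE_CATEGORIES),
                               ("mosaics", ("mosaic",))):
                pac = coupling.pac_between(
                    ep, ch_p, ch_a, cats, condition=cond,
                    n_surrogates=cfg.n_surrogates, rng=rng)
                rec = {"patient": pid, "phase_region": phase_region,
                       "amp_region": amp_region, "condition": cond,
                       "n_sig_pac": int(pac.significant.sum()),
                       "max_pac_z": float(np.nanmax(pac.z))}
                if cond == "faces" and pac.significant.any():
                    n_sig += 1
                    psi = coupling.psi_between(
                        ep, ch_p, ch_a, cats, condition=cond,
                        n_surrogates=cfg.n_surrogates, rng=rng)
                    masked = coupling.restrict_psi_to_pac(psi, pac)
                    rec["n_sig_psi"] = int(
                        np.nansum(np.abs(masked.z) >= coupling.Z_THRESHOLD))
                    np.savez(out_dir /
                             f"coupling_{pid}_{phase_region}_{amp_region}.npz",
                             pac_mi=pac.mi, pac_z=pac.z, psi=psi.psi,
                             psi_z=psi.z, psi_z_masked=masked.z)
                results.append(rec)
    table = pd.DataFrame(results)
    table.to_csv(out_dir / "coupling_summary.tsv", sep="\t", index=False)
    with open(out_dir / "coupling_axes.json", "w") as fh:
        json.dump({"phase_freqs_hz": list(coupling.PHASE_FREQS),
                   "amp_freqs_hz": list(coupling.AMP_FREQS),
                   "window_s": list(coupling.PAC_WINDOW)}, fh, indent=2)
    manifest["stages"]["coupling"] = {
        "n_computations": int(len(table)),
        "n_significant_face_pairs": int(n_sig)}


def _stage_stats(cfg, out_dir, state, manifest):
    summary = {}
    for label, rows, dep in (("erp", state.get("erp_rows"), "amplitude_uv"),
                             ("gamma", state.get("gamma_rows"), "gamma_db")):
        if rows is None:
            continue
        for region in sorted(rows["region"].unique()):
            sub = rows[rows["region"] == region]
            for model_no in (1, 2):
                table = group_stats.build_trial_table(sub, dep, model=model_no)
                spec = (group_stats.ModelSpec.model1(dep) if model_no == 1
                        else group_stats.ModelSpec.model2(dep))
                try:
                    fit = group_stats.fit_lme(table, spec)
                except ValueError as err:
                    warnings.warn(f"{label} model {model_no} in {region}: {err}")
                    continue
                stem = f"lme_{label}_model{model_no}_{region}"
                fit.terms.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
                if len(fit.contrasts):
                    fit.contrasts.to_csv(out_dir / f"{stem}_posthoc.tsv",
                                         sep="\t", index=False)
                summary[stem] = {
                    "converged": fit.converged,
                    "significant_terms": fit.terms.loc[
                        fit.terms["p_holm"] < 0.05, "term"].tolist()}

    flags = []
    erp_rows, gamma_rows = state.get("erp_rows"), state.get("gamma_rows")
    if erp_rows is not None and gamma_rows is not None:
        face_erp = erp_rows[erp_rows["category"] != "mosaic"]
        face_gm = gamma_rows[gamma_rows["category"] != "mosaic"]
        for (pid, ch), sub in face_erp.groupby(["patient", "channel"]):
            gsub = face_gm[(face_gm["patient"] == pid)
                           & (face_gm["region"] == sub["region"].iloc[0])]
            if gsub.empty:
                continue
            res = group_stats.classify_responsive(
                sub, gsub["gamma_db"].to_numpy())
            flags.append({"patient": pid, "channel": ch,
                          "region": sub["region"].iloc[0], **res})
    flag_table = pd.DataFrame(flags)
    flag_table.to_csv(out_dir / "responsive_contacts.tsv", sep="\t",
                      index=False)
    if len(flag_table):
        summary["responsive_fraction_erp"] = float(
            flag_table["erp_responsive"].mean())
        summary["responsive_fraction_gamma"] = float(
            flag_table["gamma_responsive"].mean())
    manifest["stages"]["stats"] = summary


_STAGE_FUNCS = {"simulate": _stage_simulate, "preprocess": _stage_preprocess,
                "erp": _stage_erp, "tfr": _stage_tfr,
                "cluster": _stage_cluster, "coupling": _stage_coupling,
                "stats": _stage_stats}
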