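"""End-to-end study orchestration.

``simulate_study`` writes a complete synthetic study to disk (marker/force
TSVs per trial, a trial manifest, a genotype/covariate CSV) with genotype
effects embedded in jump vigour, and ``run_pipeline`` runs the full analysis
from a :class:`StudyConfig`: per-trial outcomes, per-participant aggregation,
Hardy-Weinberg checks, and genotype association (ANOVA + Tukey, genetic-model
variance decomposition, carrier-group t-tests, likelihood-ratio covariate
tests).  Trials that fail quality control are logged and excluded; the run is
deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events, genetics, io_formats, kinematics, outcomes, synthetic
from .errors import KinegenError
from .io_formats import read_genotype_table, write_results_table
from .outcomes import AnthropometryConfig, OutcomeSet

#: pooled "carrier" group per locus for the dominant-grouping comparison
CARRIER_GROUPS = {"actn3": ("RR", "RX"), "ace": ("DD", "ID")}

DEFAULT_ASSOC_OUTCOMES = (
    "cmj_hip_rt_peak", "cmj_knee_rt_peak", "dj_hip_rt_peak", "dj_knee_rt_peak",
)


@dataclass
class StudyConfig:
    """Everything a full study run needs, loadable from YAML."""

    trial_manifest: str = ""
    genotype_csv: str = ""
    out_dir: str = "results"
    filter_cutoff_hz: float = 10.0
    segmentation_cutoff_hz: float = 20.0
    flight_threshold_n: float = 10.0
    aggregate: str = "mean"
    anthropometry: dict | None = None
    box_height_m: float = 0.20
    sex: str = "F"
    seed: int = 0
    assoc_outcomes: tuple = DEFAULT_ASSOC_OUTCOMES
    assoc_loci: tuple = ("actn3", "ace")
    assoc_models: tuple = ("additive", "I_dominant", "D_dominant")
    assoc_covariates: tuple = ("body_mass_kg", "age")


def load_study_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = StudyConfig(**raw)
    return cfg


# ---------------------------------------------------------------------------
# synthetic study on disk


def simulate_study(out_dir, n_participants: int = 20, trials_per_test: int = 2,
                   seed: int = 0, effect_size: float = 0.0,
                   model: str = "additive", target_locus: str = "ace",
                   noise_sd: float = 0.002, frequency: float = 200.0) -> StudyConfig:
    """Write a synthetic cohort study (trials + genotypes) to ``out_dir``.

    A latent per-participant "explosiveness" u = genotype shift + N(0,1) sets
    each participant's flight height and eccentric quickness, so a positive
    ``effect_size`` makes effect-allele carriers jump higher and dip faster —
    a known direction for the association stage to recover.
    """
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    cohort = synthetic.CohortSimConfig(
        n=n_participants, model=model, target_locus=target_locus,
        effect_size=effect_size, outcome_name="u", baseline_mean=0.0,
        outcome_sd=1.0, seed=seed,
    )
    geno, latent, truth = synthetic.simulate_cohort(cohort)
    geno.to_csv(out / "genotypes.csv", index=False)

    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, row in geno.iterrows():
        u = float(latent["u"].iloc[i])
        flight = float(np.clip(0.25 * (1 + 0.15 * u), 0.10, 0.45))
        t_ecc = float(np.clip(0.40 * (1 - 0.08 * u), 0.35, 0.60))
        t_contact = float(np.clip(0.20 * (1 - 0.05 * u), 0.14, 0.30))
        for jt in ("SJ", "CMJ", "DJ"):
            for k in range(1, trials_per_test + 1):
                cfg = synthetic.JumpSimConfig(
                    jump_type=jt,
                    target_flight_height=flight + float(rng.normal(0, 0.008)),
                    eccentric_duration=t_ecc,
                    contact_time=t_contact,
                    body_mass=float(row["body_mass_kg"]),
                    frequency=frequency, noise_sd=noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                )
                markers, fp, _ = synthetic.simulate_jump_trial(cfg)
                markers.trial_meta = io_formats.TrialMeta(row["id"], jt, k)
                mfile = f"trials/{row['id']}_{jt}_{k}_markers.tsv"
                ffile = f"trials/{row['id']}_{jt}_{k}_force.tsv"
                io_formats.write_marker_tsv(markers, out / mfile)
                io_formats.write_forceplate_tsv(fp, out / ffile)
                rows.append({"participant_id": row["id"], "trial_type": jt,
                             "trial_number": k, "marker_file": mfile,
                             "force_file": ffile})
        for k in range(1, trials_per_test + 1):
            scfg = synthetic.SprintSimConfig(
                v0=0.0, acceleration=float(np.clip(2.0 + 0.3 * u, 1.0, 4.0)),
                start_x=-0.5,  # a rolling start just behind gate A
                frequency=frequency, noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            markers, _ = synthetic.simulate_sprint_trial(scfg)
            markers.trial_meta = io_formats.TrialMeta(row["id"], "SPRINT", k)
            mfile = f"trials/{row['id']}_SPRINT_{k}_markers.tsv"
            io_formats.write_marker_tsv(markers, out / mfile)
            rows.append({"participant_id": row["id"], "trial_type": "SPRINT",
                         "trial_number": k, "marker_file": mfile,
                         "force_file": ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "trials.csv", index=False)
    return StudyConfig(trial_manifest=str(out / "trials.csv"),
                       genotype_csv=str(out / "genotypes.csv"),
                       out_dir=str(out / "results"), seed=seed)


# ---------------------------------------------------------------------------
# per-trial processing


def process_jump_trial(markers, fp, jump_type: str, body_mass: float,
                       anthro: AnthropometryConfig, cfg: StudyConfig) -> dict:
    """All outcomes of a single jump trial, as a flat dict."""
    markers = io_formats.fill_gaps(markers)
    seg = events.segment_jump_phases(
        markers, fp, jump_type,
        flight_threshold_n=cfg.flight_threshold_n,
        cutoff_hz=cfg.segmentation_cutoff_hz,
    )
    lin = kinematics.linear_kinematics(markers, "F_sacrum", "z",
                                       cutoff_hz=cfg.filter_cutoff_hz)
    box = cfg.box_height_m if jump_type == "DJ" else 0.0
    h_ft = events.jump_height(seg, lin, "flight_time")
    h_mk = events.jump_height(seg, lin, "marker", box_height=box)
    row: dict = {
        "height_flight_m": h_ft,
        "height_marker_m": h_mk,
        "contact_time_s": seg.contact_time,
        "flight_time_s": seg.flight_time,
    }
    if "E" in seg.phases and seg.phases["E"][1] > seg.phases["E"][0]:
        ecc = seg.phases["E"]
        for joint in ("hip", "knee"):
            ang = kinematics.joint_angle_series(
                markers, joint, side="R", cutoff_hz=cfg.filter_cutoff_hz)
            seg_mass = anthro.chain_mass(joint, body_mass)
            rt, rt_peak = outcomes.relative_torque(seg_mass, ang, body_mass, phase=ecc)
            _, p_peak = outcomes.joint_power(rt, ang.angular_velocity, phase=ecc)
            row[f"{joint}_rt_peak"] = rt_peak
            row[f"{joint}_power_peak"] = p_peak
        # RFD over movement onset -> takeoff, as force-plate sample indices
        ratio = fp.frequency / markers.frequency
        prop_fp = (int(round(seg.phases["E"][0] * ratio)),
                   int(round(seg.phases["C"][1] * ratio)))
        row["rfd"] = outcomes.rate_of_force_development(fp, prop_fp)
    if seg.contact_time is not None:
        row["ssc_class"] = events.classify_ssc_speed(seg.contact_time)
    return row


def _trial_outcome_set(pid: str, jump_type: str, row: dict) -> OutcomeSet:
    os_ = OutcomeSet(participant_id=pid)
    jt = jump_type.lower()
    if jump_type in ("SJ", "CMJ", "DJ"):
        setattr(os_, f"{jt}_height_m", row["height_flight_m"])
    if jump_type == "DJ":
        os_.dj_contact_time_s = row["contact_time_s"]
    for key in ("hip_rt_peak", "knee_rt_peak", "hip_power_peak", "knee_power_peak"):
        if key in row:
            setattr(os_, f"{jt}_{key}", row[key])
    if "rfd" in row and jump_type in ("CMJ", "DJ"):
        setattr(os_, f"{jt}_rfd", row["rfd"])
    if jump_type == "SPRINT":
        os_.sprint_time_s = row["sprint_time_s"]
    return os_


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: StudyConfig) -> dict:
    """Run the whole study analysis; returns the output file paths.

    Writes ``trial_outcomes.csv``, ``participant_outcomes.csv``, ``hwe.csv``,
    ``association.csv`` and ``run_log.txt`` under ``config.out_dir``.
    Trials that fail (unreadable, unsegmentable) are logged and skipped;
    an empty cohort after exclusions aborts the run.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"kinegen pipeline run, seed={cfg.seed}"]
    anthro = AnthropometryConfig(fractions=cfg.anthropometry) if cfg.anthropometry \
        else AnthropometryConfig()

    manifest = pd.read_csv(cfg.trial_manifest, dtype={"participant_id": str})
    base = Path(cfg.trial_manifest).parent
    geno = read_genotype_table(cfg.genotype_csv)
    mass = dict(zip(geno["id"], geno.get("body_mass_kg", pd.Series(dtype=float))))

    trial_rows: list[dict] = []
    per_participant: dict[str, list[OutcomeSet]] = {}
    for _, m in manifest.iterrows():
        pid, jt = str(m["participant_id"]), str(m["trial_type"])
        label = f"{pid}/{jt}#{m['trial_number']}"
        try:
            markers = io_formats.read_marker_tsv(base / m["marker_file"])
            if jt == "SPRINT":
                row = {"sprint_time_s": events.sprint_time(markers)}
            else:
                fp = io_formats.read_forceplate_tsv(base / m["force_file"])
                body_mass = float(mass.get(pid, 55.0) or 55.0)
                row = process_jump_trial(markers, fp, jt, body_mass, anthro, cfg)
        except (KinegenError, OSError) as exc:
            log.append(f"WARN trial {label} excluded: {exc}")
            continue
        log.append(f"OK trial {label}: " + ", ".join(
            k for k, v in row.items() if v is not None))
        trial_rows.append({"participant_id": pid, "trial_type": jt,
                           "trial_number": m["trial_number"], **row})
        per_participant.setdefault(pid, []).append(_trial_outcome_set(pid, jt, row))

    if not trial_rows:
        raise KinegenError("no trial produced outcomes; cannot continue")
    write_results_table(pd.DataFrame(trial_rows), out / "trial_outcomes.csv")

    agg_rows = []
    for pid in sorted(per_participant):
        agg = outcomes.aggregate_trials(per_participant[pid], cfg.aggregate)
        agg_rows.append(agg.as_dict())
    part = pd.DataFrame(agg_rows)
    part = part.merge(geno, left_on="participant_id", right_on="id", how="inner")

    # exclusions: questionnaire flags and sex stratum
    for flag in ("parq_positive", "power_sport"):
        if flag in part.columns:
            part = part[~part[flag].astype(bool)]
    if "sex" in part.columns and cfg.sex:
        part = part[part["sex"] == cfg.sex]
    if part.empty:
        raise KinegenError("cohort empty after exclusions")
    log.append(f"cohort after exclusions: {len(part)} participants")
    write_results_table(part.drop(columns=["id"]), out / "participant_outcomes.csv")

    # Hardy-Weinberg per locus, before association
    hwe_rows = []
    for locus in cfg.assoc_loci:
        labels = genetics.LOCUS_GENOTYPES[locus]
        counts = [int((part[locus] == g).sum()) for g in labels]
        chi2, df, p = genetics.hwe_chi_square(counts)
        hwe_rows.append({"locus": locus, **dict(zip(labels, counts)),
                         "chi2": chi2, "df": df, "p": p})
    write_results_table(pd.DataFrame(hwe_rows), out / "hwe.csv")

    assoc_rows = []
    for outcome_name in cfg.assoc_outcomes:
        if outcome_name not in part.columns or part[outcome_name].isna().all():
            log.append(f"WARN outcome {outcome_name} unavailable; skipped")
            continue
        sub = part.dropna(subset=[outcome_name])
        y = sub[outcome_name].to_numpy(dtype=float)
        for locus in cfg.assoc_loci:
            g = sub[locus].to_numpy()
            rec: dict = {"outcome": outcome_name, "locus": locus, "n": len(sub)}
            try:
                an = genetics.genotype_anova(y, g)
                rec.update(F=an.F, p_anova=an.p, eta_squared=an.eta_squared)
            except KinegenError as exc:
                log.append(f"WARN ANOVA {outcome_name}x{locus}: {exc}")
                an = None
            if an is not None and an.eta_squared > 0:
                mv = genetics.model_variance_percent(y, g, locus, cfg.assoc_models)
                for mname, pct in mv.percent_of_anova.items():
                    rec[f"pct_{mname}"] = pct
                rec["best_model"] = mv.best_model
            try:
                tt = genetics.dominant_group_ttest(y, g, CARRIER_GROUPS[locus])
                rec.update(t=tt.t, p_t=tt.p,
                           carrier_mean=tt.means[0], noncarrier_mean=tt.means[1],
                           ks_p_carrier=tt.ks_normality_p[0],
                           ks_p_noncarrier=tt.ks_normality_p[1])
            except KinegenError as exc:
                log.append(f"WARN t-test {outcome_name}x{locus}: {exc}")
            try:
                coding = genetics.model_coding("additive", locus)
                df_lrt = sub[[outcome_name] + list(cfg.assoc_covariates)].copy()
                df_lrt["genotype_code"] = genetics.code_genetic_model(g, coding)
                covs = ["genotype_code"] + [c for c in cfg.assoc_covariates
                                            if c in sub.columns]
                res = genetics.lrt_covariate(df_lrt, outcome_name, covs,
                                             "genotype_code")
                rec.update(lr=res.lr, lr_df=res.df, p_lrt=res.p)
            except (KinegenError, KeyError) as exc:
                log.append(f"WARN LRT {outcome_name}x{locus}: {exc}")
            assoc_rows.append(rec)
    write_results_table(pd.DataFrame(assoc_rows), out / "association.csv")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return {name: str(out / f"{name}.csv") for name in
            ("trial_outcomes", "participant_outcomes", "hwe", "association")} | \
           {"run_log": str(out / "run_log.txt")}
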