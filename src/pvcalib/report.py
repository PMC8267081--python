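"""End-to-end analysis pipeline: score -> criteria -> accuracy -> stats ->
banding, rendering the study-style tables as CSV files plus a run log.

Outputs, one file per table analogue:

* ``table1_base_rates.csv`` — per-component ordinal-code base rates for the
  two validity composites;
* ``table3_contrasts.csv`` — recognition-trial group contrasts by criterion
  PVT (independent t, Cohen's d, heteroscedasticity flag);
* ``table4_evi_accuracy.csv`` — cutoff sweeps of the embedded validity
  indicators against each criterion, with AUC and 95% CI;
* ``table5_ability.csv`` — the recognition scores as ability predictors
  against dichotomized ability criteria;
* ``table6_banding.csv`` — banded cumulative distributions;
* ``contrasts.csv`` and ``run_log.md``.

Every rendered cell is produced by a module operation; the log records n,
Borderline exclusions (which silently change n in dichotomous analyses),
and the rule settings used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import accuracy as acc
from . import banding, criteria, recoding, simulate, stats
from .cohort import CohortTable, read_cohort
from .errors import ConfigError

VALIDITY_CRITERIA = ("TOMM1", "WCT", "EI5_MEM", "EI5_PSP")
ABILITY_CRITERIA = criteria.ABILITY_CRITERIA
ALL_CRITERIA = VALIDITY_CRITERIA + ABILITY_CRITERIA + ("LATENT",)

_DEFAULT_EVI_CUTOFFS = {
    "rcft_copy": (25, 24, 23, 20),
    "rcft_yn": (18, 17, 16, 15),
    "rcft_fcr": (18, 17, 16, 15),
    "combined": (18, 17, 16),
}
_DEFAULT_ABILITY_CUTOFFS = {
    "rcft_copy": (28, 30, 32, 34),
    "rcft_yn": (19, 20, 21, 22),
    "rcft_fcr": (19, 20, 21, 22),
}


def default_rules() -> criteria.ValidityRuleSet:
    """The example rule file shipped with the package (its TOMM Trial-1
    cutoff is an illustrative placeholder; see the file's comments)."""
    with resources.as_file(
        resources.files("pvcalib") / "config" / "validity_rules.yaml"
    ) as p:
        return criteria.ValidityRuleSet.from_yaml(p)


@dataclass
class AnalysisConfig:
    """Pipeline configuration: where the cohort comes from, which rules and
    criteria apply, and where the report bundle goes."""

    out_dir: Path
    cohort_path: Path | None = None
    presets: tuple[str, ...] = ("clinical_2021", "student_2021")
    n: int | None = None
    seed: int = 0
    rules: criteria.ValidityRuleSet = field(default_factory=default_rules)
    evi_cutoffs: dict = field(default_factory=lambda: dict(_DEFAULT_EVI_CUTOFFS))
    ability_cutoffs: dict = field(
        default_factory=lambda: dict(_DEFAULT_ABILITY_CUTOFFS)
    )
    criterion_list: tuple[str, ...] = VALIDITY_CRITERIA + ABILITY_CRITERIA
    auc_method: str = "hanley_mcneil"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {"out_dir": Path(raw["out_dir"])}
        if "cohort_path" in raw:
            kwargs["cohort_path"] = Path(raw["cohort_path"])
        for key in ("presets", "criterion_list"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("n", "seed", "evi_cutoffs", "ability_cutoffs", "auc_method"):
            if key in raw:
                kwargs[key] = raw[key]
        if "rules" in raw:
            kwargs["rules"] = criteria.ValidityRuleSet(**raw["rules"])
        return cls(**kwargs)


def criterion_decisions(
    cohort: CohortTable,
    name: str,
    rules: criteria.ValidityRuleSet,
    specs: dict[str, recoding.CompositeSpec] | None = None,
) -> pd.Series:
    """Per-examinee Pass/Fail/Borderline/NA decisions for a named criterion.

    Validity criteria: Fail marks the criterion-positive (non-credible)
    class.  Ability criteria: Fail marks "meets the ability criterion", so
    the same positive-class convention serves both table families.
    ``LATENT`` uses the simulator's hidden status.
    """
    specs = specs or recoding.list_builtin_specs()
    ids = cohort.ids
    if name == "TOMM1":
        vals = cohort.scores("tomm1")
        out = [
            criteria.threshold_outcome(v, rules.tomm1_fail_max, criteria.FAIL_IF_LE).decision
            for v in vals
        ]
    elif name == "WCT":
        accs = cohort.scores("wct_acc")
        t2cs = cohort.scores("wct_t2c_s")
        out = [
            criteria.wct_outcome(a, t, rules).decision for a, t in zip(accs, t2cs)
        ]
    elif name in ("EI5_MEM", "EI5_PSP"):
        results = recoding.score_cohort(cohort, specs[name])
        out = [r.band for r in results]
    elif name in ABILITY_CRITERIA:
        flags = [criteria.ability_criterion(r, name, specs) for r in cohort.records]
        out = [
            "NA" if f is None else ("Fail" if f else "Pass") for f in flags
        ]
    elif name == "LATENT":
        out = [
            "NA" if r.latent_status is None
            else ("Fail" if r.latent_status == simulate.NONCREDIBLE else "Pass")
            for r in cohort.records
        ]
    else:
        raise ConfigError(
            f"unresolvable criterion {name!r} (expected one of {ALL_CRITERIA})"
        )
    return pd.Series(out, index=ids, name=name, dtype=object)


def _predictor_scores(cohort: CohortTable, predictor: str) -> pd.Series:
    if predictor == "combined":
        # worst-case of the two trials: Fail at c iff both <= c
        yn, fcr = cohort.scores("rcft_yn"), cohort.scores("rcft_fcr")
        return pd.concat([yn, fcr], axis=1).max(axis=1)
    return cohort.scores(predictor)


def _load_cohort(config: AnalysisConfig) -> CohortTable:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    parts = []
    registry = None
    for i, name in enumerate(config.presets):
        cfg = simulate.preset(name)
        if config.n is not None:
            cfg = replace(cfg, n=config.n)
        part = simulate.simulate_cohort(cfg, seed=config.seed + i)
        registry = part.registry
        parts.append(part)
    records = [r for p in parts for r in p.records]
    if not records:
        raise ConfigError("no cohort records (empty presets?)")
    return CohortTable(records, registry or parts[0].registry)


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Deterministic given the cohort (or preset + seed).  Returns the mapping
    of table name to written path.
    """
    for crit in config.criterion_list:
        if crit not in ALL_CRITERIA:
            raise ConfigError(f"unresolvable criterion {crit!r}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = recoding.list_builtin_specs()
    cohort = _load_cohort(config)
    groups = cohort.by_group()
    paths: dict[str, Path] = {}
    log: list[str] = ["# Run log", ""]
    log.append(f"records: {len(cohort)}")
    for g, sub in groups.items():
        log.append(f"group {g}: n={len(sub)}")
    log.append(f"rules: {config.rules}")
    log.append("")

    # --- table 1: component base rates of the validity composites ----------
    t1_parts = []
    for cname in ("EI5_MEM", "EI5_PSP"):
        for gname, sub in groups.items():
            if not _has_components(sub, specs[cname]):
                continue
            df = recoding.component_base_rates(sub, specs[cname]).reset_index()
            df.insert(0, "composite", cname)
            df.insert(1, "group", gname)
            t1_parts.append(df)
    table1 = pd.concat(t1_parts, ignore_index=True) if t1_parts else pd.DataFrame()
    paths["table1_base_rates"] = out_dir / "table1_base_rates.csv"
    table1.to_csv(paths["table1_base_rates"], index=False)

    # --- criterion decisions, per group -------------------------------------
    validity_crits = [c for c in config.criterion_list if c in VALIDITY_CRITERIA]
    ability_crits = [c for c in config.criterion_list if c in ABILITY_CRITERIA]

    # --- table 3: recognition scores by criterion pass/fail -----------------
    t3_rows = []
    contrast_results: dict[str, stats.ContrastResult] = {}
    for gname, sub in groups.items():
        for crit in validity_crits:
            decisions = criterion_decisions(sub, crit, config.rules, specs)
            for trial in ("rcft_yn", "rcft_fcr"):
                scores = sub.scores(trial)
                x = scores[(decisions == "Pass").reindex(scores.index, fill_value=False)].dropna()
                y = scores[(decisions == "Fail").reindex(scores.index, fill_value=False)].dropna()
                if len(x) < 2 or len(y) < 2:
                    continue
                res = stats.independent_t(x, y)
                label = f"{gname}/{crit}/{trial}"
                contrast_results[label] = res
                t3_rows.append(
                    {
                        "group": gname, "criterion": crit, "trial": trial,
                        "n_pass": res.n1, "n_fail": res.n2,
                        "pct_fail": 100 * res.n2 / (res.n1 + res.n2),
                        "mean_pass": res.mean1, "sd_pass": res.sd1,
                        "mean_fail": res.mean2, "sd_fail": res.sd2,
                        "p": res.p, "d": res.d,
                        "levene_flag": res.heteroscedastic,
                        "n_excluded_borderline": int((decisions == "Borderline").sum()),
                    }
                )
                if crit in ("EI5_MEM", "EI5_PSP"):
                    log.append(
                        f"{gname}/{crit}/{trial}: Borderline excluded = "
                        f"{int((decisions == 'Borderline').sum())}"
                    )
    paths["table3_contrasts"] = out_dir / "table3_contrasts.csv"
    pd.DataFrame(t3_rows).to_csv(paths["table3_contrasts"], index=False)

    # --- table 4: EVI cutoff sweeps against criterion PVTs -------------------
    t4_rows = []
    for gname, sub in groups.items():
        for crit in validity_crits:
            decisions = criterion_decisions(sub, crit, config.rules, specs)
            for predictor, cutoffs in config.evi_cutoffs.items():
                scores = _predictor_scores(sub, predictor)
                if scores.dropna().empty:
                    continue
                auc_res = acc.auc(
                    scores, decisions, method=config.auc_method,
                    orientation=acc.LOWER_FAILS,
                )
                sweep = acc.cutoff_sweep(
                    scores, decisions, list(cutoffs), criteria.FAIL_IF_LE
                )
                for row in sweep:
                    t4_rows.append(
                        {
                            "group": gname, "predictor": predictor,
                            "criterion": crit, "cutoff": row.cutoff,
                            "br_fail": row.br_fail, "sens": row.sens,
                            "spec": row.spec, "acc": row.acc,
                            "n": row.n_used,
                            "n_excluded": row.n_excluded_borderline,
                            "auc": auc_res.auc,
                            "auc_lo": None if auc_res.ci95 is None else auc_res.ci95[0],
                            "auc_hi": None if auc_res.ci95 is None else auc_res.ci95[1],
                            "auc_method": auc_res.method,
                        }
                    )
    paths["table4_evi_accuracy"] = out_dir / "table4_evi_accuracy.csv"
    pd.DataFrame(t4_rows).to_csv(paths["table4_evi_accuracy"], index=False)

    # --- table 5: recognition scores as ability predictors -------------------
    t5_rows = []
    for gname, sub in groups.items():
        for crit in ability_crits:
            decisions = criterion_decisions(sub, crit, config.rules, specs)
            if not (decisions == "Fail").any():
                continue
            for predictor, cutoffs in config.ability_cutoffs.items():
                scores = _predictor_scores(sub, predictor)
                if scores.dropna().empty:
                    continue
                auc_res = acc.auc(
                    scores, decisions, method=config.auc_method,
                    orientation=acc.HIGHER_FAILS,
                )
                sweep = acc.cutoff_sweep(
                    scores, decisions, list(cutoffs), criteria.FAIL_IF_GE
                )
                for row in sweep:
                    t5_rows.append(
                        {
                            "group": gname, "predictor": predictor,
                            "criterion": crit, "cutoff": row.cutoff,
                            "br_meets": row.br_fail, "sens": row.sens,
                            "spec": row.spec, "acc": row.acc, "n": row.n_used,
                            "auc": auc_res.auc,
                            "auc_lo": None if auc_res.ci95 is None else auc_res.ci95[0],
                            "auc_hi": None if auc_res.ci95 is None else auc_res.ci95[1],
                        }
                    )
    paths["table5_ability"] = out_dir / "table5_ability.csv"
    pd.DataFrame(t5_rows).to_csv(paths["table5_ability"], index=False)

    # --- table 6: banded cumulative distributions ----------------------------
    aux: dict[str, pd.Series] = {}
    vpa = recoding.score_cohort(cohort, specs["VPA3"])
    aux["vpa3"] = pd.Series(
        [float(r.value) if r.value is not None else float("nan") for r in vpa],
        index=vpa.index,
    )
    aux["hvlt_dr_t"] = cohort.scores("hvlt_dr_t")
    t6_parts = []
    for trial in ("rcft_yn", "rcft_fcr"):
        df = banding.banded_report(groups, trial, aux=aux)
        df.insert(0, "trial", trial)
        t6_parts.append(df)
    table6 = pd.concat(t6_parts, ignore_index=True)
    paths["table6_banding"] = out_dir / "table6_banding.csv"
    table6.to_csv(paths["table6_banding"], index=False)

    # --- incentive-status contrasts across groups ----------------------------
    if {"clinical", "student"} <= set(groups):
        for crit in ("TOMM1", "WCT"):
            if crit not in validity_crits:
                continue
            counts = {}
            for gname in ("clinical", "student"):
                d = criterion_decisions(groups[gname], crit, config.rules, specs)
                scoreable = d.isin(["Pass", "Fail"])
                counts[gname] = (int((d == "Fail").sum()), int(scoreable.sum()))
            (x1, n1), (x2, n2) = counts["clinical"], counts["student"]
            if n1 and n2:
                contrast_results[f"br_fail_z/{crit}"] = stats.two_proportion_z(
                    x1, n1, x2, n2
                )
    paths["contrasts"] = out_dir / "contrasts.csv"
    stats.contrasts_frame(contrast_results).to_csv(paths["contrasts"], index=False)

    paths["run_log"] = out_dir / "run_log.md"
    paths["run_log"].write_text("\n".join(log) + "\n")
    return paths


def _has_components(cohort: CohortTable, spec: recoding.CompositeSpec) -> bool:
    present = set()
    for r in cohort.records:
        present.update(r.scores)
    return any(rule.instrument in present for rule in spec.components)
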