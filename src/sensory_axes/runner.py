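"""Orchestration of the full axis analysis on one cohort.

``run_analysis`` executes the analysis sequence:

1. score all instruments (quadrant sums, normative categories, axis
   scores, derived quadrants, highest-raw-score quadrant, personality
   axes);
2. axis/quadrant agreement -- Fisher's exact test per axis (sign of the
   calculated score vs the axis group of the highest-raw quadrant, with
   Cramer's V) and a chi-squared test of highest vs derived quadrant;
3. per behavioral-response group and per threshold group, one-way ANOVA
   of the calculated axis score across normative categories, with Tukey
   post hoc;
4. t-test of introversion/extraversion by passive/active group (effect
   size r);
5. ERP pipeline, then t-tests of P50 amplitude and gating ratio by
   low/high threshold group and Pearson correlations of the threshold
   axis score against both (criterion-filtered).

Participants with a tied highest raw score are excluded from
quadrant-categorical analyses; participants without EEG, or whose
(conditioning) P50 falls below the 0.5 uV criterion, are excluded from
the respective ERP analyses only.  Every exclusion is logged with its
reason; degenerate tests are skipped and logged rather than fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import stats as sx
from .epq import EPQItemMap, default_epq_map, score_epq
from .profile import (
    CATEGORIES,
    QUADRANTS,
    ItemMap,
    NormativeTable,
    ResponseSet,
    axis_groups,
    axis_scores,
    categorize,
    default_item_map,
    derived_quadrant,
    highest_quadrant,
    score_quadrants,
)
from .serp import Recording, SerpParams, SerpResult, run_serp
from .simulate import CohortSpec, EEGSimSpec, simulate_epq_responses, simulate_responses


@dataclass
class Participant:
    participant_id: str
    responses: ResponseSet
    epq: Optional[Mapping[str, int]] = None
    recording_single: Optional[Recording] = None
    recording_pairs: Optional[Recording] = None
    serp: Optional[SerpResult] = None
    truth: Optional[Dict[str, float]] = None


@dataclass
class CohortDataset:
    participants: List[Participant]
    item_map: ItemMap
    epq_map: Optional[EPQItemMap] = None

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")


@dataclass
class AnalysisReport:
    scores: pd.DataFrame
    tests: Dict[str, sx.TestResult] = field(default_factory=dict)
    anova_groups: Dict[str, pd.DataFrame] = field(default_factory=dict)
    tukey: Dict[str, Dict[Tuple[str, str], sx.TestResult]] = field(default_factory=dict)
    exclusions: List[Tuple[str, str]] = field(default_factory=list)
    skipped: List[Tuple[str, str]] = field(default_factory=list)
    counts: Dict[str, int] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Axis analysis report", "====================", ""]
        lines.append(f"participants: {self.counts.get('n_input', 0)} in, "
                     f"{self.counts.get('n_quadrant_included', 0)} in quadrant analyses")
        lines.append("")
        for name, t in self.tests.items():
            df = t.df if t.df is not None else ""
            eff = f", {t.effect_name} = {t.effect_value:.3f}" if t.effect_value is not None else ""
            lines.append(f"{name}: stat = {t.statistic:.3f}, df = {df}, p = {t.pvalue:.4g}{eff}")
        for key, table in self.anova_groups.items():
            lines.append("")
            lines.append(f"ANOVA table [{key}]:")
            lines.append(table.to_string(index=False))
        if self.exclusions:
            lines.append("")
            lines.append("exclusions:")
            for pid, reason in self.exclusions:
                lines.append(f"  {pid}: {reason}")
        if self.skipped:
            lines.append("")
            lines.append("skipped tests:")
            for name, reason in self.skipped:
                lines.append(f"  {name}: {reason}")
        return "\n".join(lines)

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.tests.items():
            rows.append(
                {
                    "test": name,
                    "kind": t.name,
                    "statistic": t.statistic,
                    "df": str(t.df) if t.df is not None else "",
                    "p": t.pvalue,
                    "effect_name": t.effect_name or "",
                    "effect_value": t.effect_value if t.effect_value is not None else "",
                }
            )
        for key, pairs in self.tukey.items():
            for (a, b), t in pairs.items():
                rows.append(
                    {
                        "test": f"tukey[{key}] {a} vs {b}",
                        "kind": t.name,
                        "statistic": t.statistic,
                        "df": "",
                        "p": t.pvalue,
                        "effect_name": "",
                        "effect_value": "",
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.tests_frame().to_csv(out / "tests.csv", index=False)
        pd.DataFrame(self.exclusions, columns=["participant_id", "reason"]).to_csv(
            out / "exclusions.csv", index=False
        )
        for key, table in self.anova_groups.items():
            table.to_csv(out / f"anova_{key}.csv", index=False)
        (out / "summary.txt").write_text(self.summary() + "\n")


def _score_table(data: CohortDataset, norms: NormativeTable, serp_params: SerpParams,
                 exclusions: List[Tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for p in data.participants:
        raw = score_quadrants(p.responses, data.item_map)
        cats = categorize(raw, norms)
        axes = axis_scores(p.responses, data.item_map)
        derived = derived_quadrant(axes)
        hq = highest_quadrant(raw)
        row: Dict[str, object] = {"participant_id": p.participant_id}
        for q in QUADRANTS:
            row[f"raw_{q}"] = raw[q]
        for q in QUADRANTS:
            row[f"cat_{q}"] = cats[q]
        row["br"] = axes.br
        row["t"] = axes.t
        row["derived_quadrant"] = derived
        row["highest_quadrant"] = hq.quadrant or ""
        row["tie_flag"] = hq.tie
        if hq.tie:
            exclusions.append((p.participant_id, "tie"))
            row["br_group"] = ""
            row["t_group"] = ""
            row["highest_category"] = ""
        else:
            br_g, t_g = axis_groups(hq.quadrant)
            row["br_group"] = br_g
            row["t_group"] = t_g
            row["highest_category"] = cats[hq.quadrant]
        if p.epq is not None and data.epq_map is not None:
            e = score_epq(p.epq, data.epq_map)
            row["ie"] = e.ie
            row["neuroticism"] = e.neuroticism
        else:
            row["ie"] = np.nan
            row["neuroticism"] = np.nan

        serp = p.serp
        if serp is None and (p.recording_single is not None or p.recording_pairs is not None):
            serp = SerpResult()
            if p.recording_single is not None:
                res = run_serp(p.recording_single, serp_params)
                serp.single = res.single
                serp.counts.update(res.counts)
            if p.recording_pairs is not None:
                res = run_serp(p.recording_pairs, serp_params)
                serp.conditioning = res.conditioning
                serp.test = res.test
                serp.gating = res.gating
                serp.counts.update(res.counts)
        row["p50_amp_uV"] = serp.single.amplitude if serp and serp.single else np.nan
        row["p50_latency_ms"] = serp.single.latency_ms if serp and serp.single else np.nan
        row["meets_criterion"] = bool(serp.single.meets_criterion) if serp and serp.single else False
        row["c_amp"] = serp.gating.c_amplitude if serp and serp.gating else np.nan
        row["t_amp"] = serp.gating.t_amplitude if serp and serp.gating else np.nan
        row["ratio"] = (
            serp.gating.ratio if serp and serp.gating and serp.gating.valid else np.nan
        )
        row["gating_valid"] = bool(serp.gating.valid) if serp and serp.gating else False
        row["has_eeg"] = serp is not None
        if serp is None:
            exclusions.append((p.participant_id, "missing_eeg"))
        rows.append(row)
    return pd.DataFrame(rows)


def _anova_block(
    scores: pd.DataFrame,
    group_col: str,
    group_val: str,
    value_col: str,
    report: AnalysisReport,
) -> None:
    key = f"{group_val}_{value_col}"
    sub = scores[(scores[group_col] == group_val) & (~scores["tie_flag"])]
    groups = {
        cat: sub.loc[sub["highest_category"] == cat, value_col].to_numpy(dtype=float)
        for cat in CATEGORIES
        if (sub["highest_category"] == cat).any()
    }
    table = pd.DataFrame(
        {
            "category": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean": [float(np.mean(v)) for v in groups.values()],
            "sd": [float(np.std(v, ddof=1)) if len(v) > 1 else np.nan for v in groups.values()],
        }
    )
    report.anova_groups[key] = table
    usable = {k: v for k, v in groups.items() if len(v) >= 1}
    try:
        report.tests[f"anova_{key}"] = sx.one_way_anova(usable)
    except sx.StatsError as err:
        report.skipped.append((f"anova_{key}", str(err)))
        return
    tukey_groups = {k: v for k, v in usable.items() if len(v) >= 2}
    if len(tukey_groups) >= 2:
        try:
            report.tukey[key] = sx.tukey_hsd(tukey_groups)
        except Exception as err:  # degenerate spread
            report.skipped.append((f"tukey_{key}", str(err)))


def run_analysis(
    data: CohortDataset,
    norms: NormativeTable,
    serp_params: SerpParams = SerpParams(),
    fisher_seed: int = 0,
) -> AnalysisReport:
    """Run the complete analysis; a pure function of its inputs."""
    exclusions: List[Tuple[str, str]] = []
    scores = _score_table(data, norms, serp_params, exclusions)
    report = AnalysisReport(scores=scores, exclusions=exclusions)
    report.counts["n_input"] = len(scores)
    ok = ~scores["tie_flag"]
    report.counts["n_quadrant_included"] = int(ok.sum())
    report.counts["n_excluded_tie"] = int(scores["tie_flag"].sum())

    # (2) axis alignment: sign of calculated score vs highest-quadrant group
    for axis, group_col, neg_label, pos_label in (
        ("br", "br_group", "passive", "active"),
        ("t", "t_group", "low", "high"),
    ):
        sub = scores[ok & (scores[axis] != 0)]
        for pid in scores.loc[ok & (scores[axis] == 0), "participant_id"]:
            report.exclusions.append((pid, f"zero_{axis}_score"))
        sign = np.where(sub[axis] > 0, pos_label, neg_label)
        try:
            table = sx.ContingencyTable.from_pairs(list(sub[group_col]), list(sign))
            fisher = sx.fisher_exact(table, seed=fisher_seed)
            chi = sx.chi_square(table)
            report.tests[f"{axis}_alignment_fisher"] = sx.TestResult(
                name=fisher.name,
                statistic=fisher.statistic,
                df=fisher.df,
                pvalue=fisher.pvalue,
                effect_name="cramers_v",
                effect_value=chi.effect_value,
                extra=fisher.extra,
            )
        except sx.StatsError as err:
            report.skipped.append((f"{axis}_alignment_fisher", str(err)))

    # (2b) quadrant agreement: highest-raw vs derived quadrant
    sub = scores[ok & (scores["derived_quadrant"] != "unclassified")]
    for pid in scores.loc[ok & (scores["derived_quadrant"] == "unclassified"), "participant_id"]:
        report.exclusions.append((pid, "unclassified_derived_quadrant"))
    try:
        table = sx.ContingencyTable.from_pairs(
            list(sub["highest_quadrant"]), list(sub["derived_quadrant"])
        )
        report.tests["quadrant_agreement_chi2"] = sx.chi_square(table)
        report.counts["n_quadrant_agreement"] = int(table.counts.sum())
    except sx.StatsError as err:
        report.skipped.append(("quadrant_agreement_chi2", str(err)))

    # (3) ordinality: axis score across normative categories within groups
    for group_val in ("passive", "active"):
        _anova_block(scores, "br_group", group_val, "br", report)
    for group_val in ("low", "high"):
        _anova_block(scores, "t_group", group_val, "t", report)

    # (4) introversion/extraversion by behavioral-response group
    with_epq = scores[ok & scores["ie"].notna()]
    a = with_epq.loc[with_epq["br_group"] == "passive", "ie"].to_numpy(dtype=float)
    b = with_epq.loc[with_epq["br_group"] == "active", "ie"].to_numpy(dtype=float)
    if len(a) >= 1 and len(b) >= 1 and len(a) + len(b) >= 3:
        try:
            report.tests["ie_by_br_group_ttest"] = sx.t_test_ind(a, b)
        except sx.StatsError as err:
            report.skipped.append(("ie_by_br_group_ttest", str(err)))
    else:
        report.skipped.append(("ie_by_br_group_ttest", "empty group"))

    # (5) ERP measures by threshold group, and correlations with the T score
    eeg = scores[ok & scores["has_eeg"]]
    singles = eeg[eeg["meets_criterion"]]
    for pid in eeg.loc[~eeg["meets_criterion"], "participant_id"]:
        report.exclusions.append((pid, "subcriterion_single_p50"))
    report.counts["n_single_included"] = len(singles)
    gate = eeg[eeg["gating_valid"]]
    for pid in eeg.loc[eeg["has_eeg"] & ~eeg["gating_valid"], "participant_id"]:
        report.exclusions.append((pid, "subcriterion_conditioning_p50"))
    report.counts["n_gating_included"] = len(gate)

    for name, frame, col in (
        ("p50_amplitude", singles, "p50_amp_uV"),
        ("gating_ratio", gate, "ratio"),
    ):
        lo = frame.loc[frame["t_group"] == "low", col].to_numpy(dtype=float)
        hi = frame.loc[frame["t_group"] == "high", col].to_numpy(dtype=float)
        if len(lo) >= 1 and len(hi) >= 1 and len(lo) + len(hi) >= 3:
            try:
                report.tests[f"{name}_by_t_group_ttest"] = sx.t_test_ind(lo, hi)
            except sx.StatsError as err:
                report.skipped.append((f"{name}_by_t_group_ttest", str(err)))
        else:
            report.skipped.append((f"{name}_by_t_group_ttest", "empty group"))
        if len(frame) >= 3:
            try:
                report.tests[f"{name}_vs_t_score_pearson"] = sx.pearson(
                    frame["t"].to_numpy(dtype=float), frame[col].to_numpy(dtype=float)
                )
            except sx.StatsError as err:
                report.skipped.append((f"{name}_vs_t_score_pearson", str(err)))
        else:
            report.skipped.append((f"{name}_vs_t_score_pearson", "n < 3"))

    return report


def make_synthetic_dataset(
    n: int = 139,
    seed: int = 0,
    cohort_spec: Optional[CohortSpec] = None,
    with_eeg: bool = True,
    n_single: int = 200,
    n_pairs: int = 200,
    inter_pair_s: float = 1.5,
    missing_eeg: int = 1,
    amplitude_median_uv: float = 0.45,
    amplitude_log_sd: float = 0.7,
    gating_mean: float = 0.77,
    gating_sd: float = 0.3,
    serp_params: SerpParams = SerpParams(),
) -> Tuple[CohortDataset, pd.DataFrame]:
    """Assemble a full synthetic cohort (questionnaires + optional EEG).

    Per-participant evoked amplitudes are lognormal around a sub-criterion
    median so that, as in real low-intensity stimulation data, only part of
    the cohort shows a measurable P50; gating factors are normal around
    0.77, clipped into [0.05, 1].  EEG is simulated and immediately reduced
    to its :class:`SerpResult` (the continuous recordings are not kept).

    Returns the dataset plus a ground-truth table (archetype, amplitude,
    gating factor per participant).
    """
    spec = cohort_spec or CohortSpec(n=n, seed=seed)
    if spec.n != n:
        spec = CohortSpec(n=n, weights=spec.weights, seed=spec.seed)
    item_map = default_item_map()
    epq_map = default_epq_map()
    rng = np.random.default_rng(seed)
    responses, labels = simulate_responses(spec, item_map, rng=rng)
    epq_ratings = simulate_epq_responses(labels, epq_map, spec, rng=rng)

    no_eeg_idx = set()
    if with_eeg and missing_eeg > 0:
        no_eeg_idx = set(rng.choice(n, size=min(missing_eeg, n), replace=False).tolist())

    participants: List[Participant] = []
    truth_rows = []
    for i, (resp, label) in enumerate(zip(responses, labels)):
        amp = float(np.exp(np.log(amplitude_median_uv) + amplitude_log_sd * rng.standard_normal()))
        g = float(np.clip(rng.normal(gating_mean, gating_sd), 0.05, 1.0))
        serp: Optional[SerpResult] = None
        if with_eeg and i not in no_eeg_idx:
            from .simulate import simulate_eeg  # local import keeps module load light

            s_seed = int(rng.integers(2**31 - 2))
            rec_single = simulate_eeg(
                EEGSimSpec(paradigm="single_train", n_stimuli=n_single,
                           amplitude_uv=amp, seed=s_seed)
            )
            rec_pairs = simulate_eeg(
                EEGSimSpec(paradigm="pairs", n_stimuli=n_pairs, amplitude_uv=amp,
                           gating=g, inter_pair_s=inter_pair_s, seed=s_seed + 1)
            )
            serp = SerpResult()
            res_s = run_serp(rec_single, serp_params)
            serp.single = res_s.single
            serp.counts.update({f"single_{k}": v for k, v in res_s.counts.items()})
            res_p = run_serp(rec_pairs, serp_params)
            serp.conditioning = res_p.conditioning
            serp.test = res_p.test
            serp.gating = res_p.gating
        participants.append(
            Participant(
                participant_id=resp.participant_id,
                responses=resp,
                epq=epq_ratings[i],
                serp=serp,
            )
        )
        truth_rows.append(
            {
                "participant_id": resp.participant_id,
                "archetype": label,
                "amplitude_uv": amp,
                "gating": g,
                "has_eeg": with_eeg and i not in no_eeg_idx,
            }
        )
    dataset = CohortDataset(participants=participants, item_map=item_map, epq_map=epq_map)
    return dataset, pd.DataFrame(truth_rows)
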