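"""End-to-end orchestration: ratings CSV in, statistics report out.

Composes the stages in the order a rating study is analysed: per-image
summaries, per-image mixture fits with BIC model selection, the
high-/low-variance quartet searches, quartet variance contrasts,
test-retest reliability, and estimation-accuracy correlations.  Every
stage logs its filter and exclusion counts; the same config and inputs
always produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

from . import data as dm
from . import mixture as mx
from . import quartets as qs
from . import stats as st

CONFIG_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class PipelineConfig:
    """One serialized, versioned document describing a full analysis run."""

    ratings_path: str
    output_dir: str
    estimations_path: str | None = None
    number_sets_path: str | None = None
    # mixture options
    sigma: float = mx.DEFAULT_SIGMA
    count_scale: float | None = None          # None -> histogram total
    bic_sample_size: str = "bins"             # "bins" | "total"
    k_list: tuple[int, ...] = (1, 2, 3)
    # quartet search
    beauty_mean_range: tuple[float, float] = (3.5, 4.0)
    typicality_min: float = 3.0
    quantile: float = 0.25
    exclusions: tuple[str, ...] = ()
    # statistics
    sd_contrast_alternative: str = "greater"  # high-variance SD > low-variance SD
    mean_contrast_alternative: str = "greater"
    exclusion_threshold: float = dm.OUTLIER_ESTIMATED_MEAN
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config_version"] = CONFIG_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        version = d.pop("config_version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise PipelineError(f"unsupported config_version {version}")
        for key in ("k_list", "exclusions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("beauty_mean_range") is not None:
            d["beauty_mean_range"] = tuple(d["beauty_mean_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _test_result_dict(t: st.TestResult) -> dict:
    return dataclasses.asdict(t)


def _corr_dict(c: st.CorrelationResult) -> dict:
    return dataclasses.asdict(c)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage the config's inputs support; return the report.

    Writes ``report.json``, ``summary.txt`` and per-stage CSVs into the
    output directory.  Stages gated on optional inputs (estimations,
    number sets, a second session) are marked ``"not run"`` in the
    report rather than silently dropped.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.to_dict(), "log": []}
    log = report["log"].append

    # -- load ---------------------------------------------------------------
    try:
        table = dm.read_ratings(config.ratings_path)
    except (OSError, ValueError) as exc:
        raise PipelineError(f"stage=load ratings={config.ratings_path}: {exc}") from exc
    log(f"loaded {len(table)} rating records, {len(table.image_ids)} images, "
        f"{len(table.participant_ids)} participants")

    # -- image summaries ----------------------------------------------------
    summaries = dm.summarize_images(table, session=1)
    dm.summaries_to_frame(summaries).to_csv(out_dir / "image_summaries.csv", index=False)
    report["image_summaries"] = [dataclasses.asdict(s) for s in summaries]

    # -- mixture fits + model selection -------------------------------------
    selection: dict[str, Any] = {}
    for s in summaries:
        hist = dm.histogram(table, s.image_id, session=1)
        cmp_ = mx.fit_and_compare(hist, ks=config.k_list, sigma=config.sigma,
                                  count_scale=config.count_scale,
                                  bic_sample_size=config.bic_sample_size)  # type: ignore[arg-type]
        selection[s.image_id] = {
            "counts": list(hist.counts),
            "selected_k": cmp_.best_k,
            "delta_bic": cmp_.delta_bic,
            "evidence": cmp_.evidence,
            "fits": [{"k": f.k, "nll": f.nll, "bic": f.bic,
                      "weights": list(f.spec.weights), "means": list(f.spec.means),
                      "converged": f.converged} for f in cmp_.fits],
        }
    report["model_selection"] = selection
    log(f"fitted mixture variants k={list(config.k_list)} to {len(selection)} images")

    # -- quartet search ------------------------------------------------------
    report["quartet_search"] = {}
    chosen: dict[str, tuple[str, ...]] = {}
    for mode in ("high_variance", "low_variance"):
        criteria = qs.SearchCriteria(beauty_mean_range=config.beauty_mean_range,
                                     typicality_min=config.typicality_min,
                                     quantile=config.quantile, mode=mode,
                                     exclusions=frozenset(config.exclusions))
        try:
            ranked = qs.search_quartets(table, summaries, criteria)
        except ValueError as exc:
            report["quartet_search"][mode] = {"status": "not run", "reason": str(exc)}
            log(f"quartet search ({mode}) skipped: {exc}")
            continue
        qs.candidates_to_frame(ranked).to_csv(out_dir / f"quartets_{mode}.csv",
                                              index=False)
        top = ranked[0]
        chosen[mode] = top.image_ids
        report["quartet_search"][mode] = {
            "status": "ok",
            "n_candidates_ranked": len(ranked),
            "top": {"image_ids": list(top.image_ids), "range_stat": top.range_stat,
                    "group_sd_mean": top.group_sd_mean,
                    "n_participants": top.n_participants},
        }
        log(f"quartet search ({mode}): {len(ranked)} candidates ranked, "
            f"top = {top.image_ids}")

    # -- quartet variance contrasts ------------------------------------------
    if len(chosen) == 2:
        hi, lo = chosen["high_variance"], chosen["low_variance"]
        sd_alt = config.sd_contrast_alternative
        mean_alt = config.mean_contrast_alternative
        sds_hi = st.group_sds(table, hi).to_numpy()
        sds_lo = st.group_sds(table, lo).to_numpy()
        mean_of = {s.image_id: s.beauty_mean for s in summaries}
        means_hi = [mean_of[i] for i in hi]
        means_lo = [mean_of[i] for i in lo]
        nsd_hi = st.group_sds(table, hi, normalized=True).to_numpy()
        nsd_lo = st.group_sds(table, lo, normalized=True).to_numpy()
        report["quartet_contrasts"] = {
            "group_sd_two_sample": _test_result_dict(
                st.two_sample_t_one_sided(sds_hi, sds_lo, alternative=sd_alt)),
            "mean_two_sample": _test_result_dict(
                st.two_sample_t_one_sided(means_hi, means_lo, alternative=mean_alt)),
            # pairing convention: images paired by their within-quartet index
            "mean_paired": _test_result_dict(
                st.paired_t_one_sided(means_hi, means_lo, alternative=mean_alt)),
            "group_sd_paired": _test_result_dict(
                st.paired_t_one_sided(sds_hi, sds_lo, alternative=sd_alt)),
            "normalized_sd_paired": _test_result_dict(
                st.paired_t_one_sided(nsd_hi, nsd_lo, alternative=sd_alt)),
        }
        log("quartet contrasts computed (two-sample and paired, raw and normalized)")
    else:
        report["quartet_contrasts"] = {"status": "not run",
                                       "reason": "need both quartet searches"}

    # -- reliability ---------------------------------------------------------
    if not table.session(2).empty:
        rel: dict[str, Any] = {"all_images": _corr_dict(st.test_retest(table))}
        for mode, quartet in sorted(chosen.items()):
            rel[mode] = _corr_dict(st.test_retest(table, image_subset=list(quartet)))
        report["reliability"] = rel
        log("test-retest reliability computed")
    else:
        report["reliability"] = {"status": "not run", "reason": "no session-2 ratings"}

    # -- estimation accuracy -------------------------------------------------
    if config.estimations_path is not None:
        try:
            records = dm.read_estimations(config.estimations_path)
        except (OSError, ValueError) as exc:
            raise PipelineError(
                f"stage=estimation file={config.estimations_path}: {exc}") from exc
        acc: dict[str, Any] = {}
        quartet_recs = [r for r in records if r.target_kind == "quartet"]
        for qid in sorted({r.target_id for r in quartet_recs}):
            sub = [r for r in quartet_recs if r.target_id == qid]
            entry = {}
            for measure in ("mean", "sd"):
                res = st.estimation_accuracy(sub, measure,  # type: ignore[arg-type]
                                             exclusion_threshold=config.exclusion_threshold)
                entry[measure] = _corr_dict(res.correlation)
                entry[f"{measure}_n_excluded"] = res.n_excluded
            acc[qid] = entry
            log(f"estimation accuracy for quartet {qid}: "
                f"{entry['mean_n_excluded']} record(s) excluded (mean >= "
                f"{config.exclusion_threshold})")
        report["estimation_accuracy"] = acc

        if config.number_sets_path is not None:
            sets = dm.read_number_sets(config.number_sets_path)
            ns_report = st.number_set_stats(sets, records)
            ns_report.actuals.to_csv(out_dir / "number_set_actuals.csv", index=False)
            report["number_sets"] = {
                str(size): {m: _corr_dict(c) for m, c in by_measure.items()}
                for size, by_measure in ns_report.accuracy_by_size.items()}
            log(f"number-set accuracy computed for sizes "
                f"{sorted(ns_report.accuracy_by_size)}")
        else:
            report["number_sets"] = {"status": "not run",
                                     "reason": "no number-sets file"}
    else:
        report["estimation_accuracy"] = {"status": "not run",
                                         "reason": "no estimations file"}
        report["number_sets"] = {"status": "not run", "reason": "no estimations file"}

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out_dir / "summary.txt").write_text(render_summary(report))
    return report


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_summary(report: dict[str, Any]) -> str:
    """One-page plain-text summary of a report bundle.

    Statistics are rounded to two decimals for display only; stages that
    did not run are marked explicitly.
    """
    lines = ["Beauty-variance analysis summary",
             "=" * 32, ""]

    lines.append("Quartet search")
    qsr = report.get("quartet_search", {})
    for mode in ("high_variance", "low_variance"):
        entry = qsr.get(mode)
        if not entry or entry.get("status") != "ok":
            lines.append(f"  {mode}: not run")
            continue
        top = entry["top"]
        lines.append(f"  {mode}: top quartet {', '.join(top['image_ids'])} "
                     f"(range stat {_fmt(top['range_stat'])}, "
                     f"group SD {_fmt(top['group_sd_mean'])})")

    lines.append("")
    lines.append("Quartet contrasts")
    qc = report.get("quartet_contrasts", {})
    if qc.get("status") == "not run" or not qc:
        lines.append("  not run")
    else:
        for name, label in (("group_sd_two_sample", "group SD (two-sample)"),
                            ("mean_two_sample", "mean beauty (two-sample)"),
                            ("mean_paired", "mean beauty (paired)"),
                            ("group_sd_paired", "group SD (paired)"),
                            ("normalized_sd_paired", "normalized SD (paired)")):
            t = qc[name]
            lines.append(f"  {label}: t({t['df']:.0f}) = {_fmt(t['statistic'])}, "
                         f"p = {_fmt(t['p_value'])}, d = {_fmt(t['cohens_d'])}")

    lines.append("")
    lines.append("Model selection (BIC)")
    sel = report.get("model_selection", {})
    if not sel:
        lines.append("  not run")
    for image_id in sorted(sel):
        e = sel[image_id]
        lines.append(f"  {image_id}: k = {e['selected_k']} "
                     f"(dBIC = {_fmt(e['delta_bic'])}, {e['evidence']})")

    lines.append("")
    lines.append("Test-retest reliability")
    rel = report.get("reliability", {})
    if rel.get("status") == "not run" or not rel:
        lines.append("  not run")
    else:
        for key in sorted(rel):
            c = rel[key]
            lines.append(f"  {key}: r = {_fmt(c['r'])}, n = {c['n']}, "
                         f"p = {_fmt(c['p_value'])}")

    lines.append("")
    lines.append("Estimation accuracy")
    acc = report.get("estimation_accuracy", {})
    if acc.get("status") == "not run" or not acc:
        lines.append("  not run")
    else:
        for qid in sorted(acc):
            e = acc[qid]
            lines.append(f"  {qid}: mean r = {_fmt(e['mean']['r'])} "
                         f"(excluded {e['mean_n_excluded']}), "
                         f"SD r = {_fmt(e['sd']['r'])}")
    ns = report.get("number_sets", {})
    if ns and ns.get("status") != "not run":
        for size in sorted(ns, key=int):
            e = ns[size]
            lines.append(f"  number sets (n={size}): mean r = {_fmt(e['mean']['r'])}, "
                         f"SD r = {_fmt(e['sd']['r'])}")
    else:
        lines.append("  number sets: not run")

    return "\n".join(lines) + "\n"
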