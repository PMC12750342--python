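"""End-to-end orchestration: simulate → split → fit → ST → HT → evaluate.

One :class:`RunConfig` drives the whole derivation. All randomness flows
from a single root seed split into named substreams (generation, split),
so a rerun with the same config writes byte-identical JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__, reference
from .core import (
    PH_BINS,
    Dataset,
    load_regulatory_limits,
    reject_unbinned,
    split_dataset,
    write_paired_table,
)
from .evaluation import (
    misclassification_rates,
    quadrant_classify,
    round_half_up,
    score_criteria,
    classify_quality,
    tally_classes,
)
from .regression import (
    fit_transfer_model,
    relative_importance,
    resolve_collinearity,
    screen_predictors,
    transformed_design,
    validate_model,
)
from .safety import derive_st_table, means_from_data
from .simulate import GeneratorConfig, generate_rice, generate_soils
from .ssd import compute_bcf, derive_ht, empirical_cumulative, fit_logistic_ssd

log = logging.getLogger("paddythresh")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    n_validation: int = 9
    limits_path: str | None = None
    means_source: str = "fixed"  # "fixed" (regional means) or "from-data"
    plotting_position: str = "hazen"
    fix_a_at_100: bool = True
    output_dir: str = "paddythresh_run"


def _substream_seeds(root: int, n: int) -> list[int]:
    children = np.random.SeedSequence(root).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full derivation and persist versioned JSON artifacts.

    Returns the run report (also written to ``evaluation.json`` /
    ``thresholds.json`` under ``config.output_dir``).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen_seed, split_seed = _substream_seeds(config.seed, 2)
    stage = "simulate"
    try:
        gcfg = replace(config.generator, seed=gen_seed)
        soils = generate_soils(gcfg)
        rice_seed = _substream_seeds(gen_seed, 1)[0]
        dataset = generate_rice(soils, noise_sd=gcfg.noise_sd, seed=rice_seed)
        write_paired_table(dataset, out_dir / "dataset.csv")
        log.info("simulated %d sites", len(dataset))

        stage = "split"
        dataset = split_dataset(dataset, config.n_validation, split_seed)

        stage = "fit"
        limits = load_regulatory_limits(config.limits_path)
        models, validations, importances = {}, {}, {}
        for el in ("Cd", "As"):
            screened = screen_predictors(
                Dataset(dataset.modeling_frame()), el
            )
            design = transformed_design(dataset.modeling_frame(), screened)
            kept = resolve_collinearity(design)
            model = fit_transfer_model(dataset, el, kept)
            models[el] = model
            model.save(out_dir / f"model_{el}.json")
            validations[el] = validate_model(model, dataset)
            importances[el] = relative_importance(model, dataset.modeling_frame())
            log.info(
                "%s model: n=%d adj_R2=%.3f predictors=%s",
                el, model.n_fit, model.adj_r2, kept,
            )

        stage = "derive-st"
        means = (
            reference.COVARIATE_MEANS
            if config.means_source == "fixed"
            else means_from_data(dataset)
        )
        thresholds = derive_st_table(models, limits, means, aux=reference.AAS_RELATION)

        stage = "derive-ht"
        binned = Dataset(reject_unbinned(dataset.frame))
        ssd_fits = {}
        for t in thresholds:
            b = next(pb for pb in PH_BINS if pb.label == t.ph_bin)
            sub = binned.frame[binned.frame["pH"].map(lambda p: b.contains(float(p)))]
            records = compute_bcf(sub, t.element, config.plotting_position)
            x, y = empirical_cumulative(
                [r.inv_bcf for r in records], config.plotting_position
            )
            fit = fit_logistic_ssd(
                x, y,
                fix_a=100.0 if config.fix_a_at_100 else None,
                element=t.element, ph_bin=t.ph_bin,
            )
            ssd_fits[(t.element, t.ph_bin)] = fit
            mac = limits[(t.element, t.ph_bin)].mac
            t.hc95_inv_bcf, t.ht = derive_ht(fit, mac)
            t.provenance["ssd"] = fit.to_dict()
        _dump(
            {"schema_version": SCHEMA_VERSION,
             "thresholds": [t.to_dict() for t in thresholds]},
            out_dir / "thresholds.json",
        )

        stage = "evaluate"
        report = {"schema_version": SCHEMA_VERSION, "elements": {}}
        for el in ("Cd", "As"):
            rsv_by_bin = {b.label: limits[(el, b.label)].rsv for b in PH_BINS}
            mac = limits[(el, PH_BINS[0].label)].mac
            quad = quadrant_classify(binned, el, rsv_by_bin, mac)
            acc, fp, fn = misclassification_rates(quad)
            scores = score_criteria(binned, el, limits, thresholds)
            report["elements"][el] = {
                "rsv_quadrants": quad.counts,
                "rsv_rates": {
                    "accuracy": round_half_up(acc),
                    "false_positive": round_half_up(fp),
                    "false_negative": round_half_up(fn),
                },
                "criterion_scores": [
                    {
                        "ph_bin": s.ph_bin, "criterion": s.criterion,
                        "value": s.value, "n": s.n,
                        "accuracy": round_half_up(s.accuracy),
                        "false_positive": round_half_up(s.false_positive_rate),
                        "false_negative": round_half_up(s.false_negative_rate),
                    }
                    for s in scores
                ],
                "validation": {
                    "n": validations[el].n_validation,
                    "r2": validations[el].r2,
                    "rmse": validations[el].rmse,
                },
                "relative_importance": importances[el],
            }
        national = {
            el: {b.label: (limits[(el, b.label)].rsv, limits[(el, b.label)].riv)
                 for b in PH_BINS}
            for el in ("Cd", "As")
        }
        regional = {
            el: {t.ph_bin: (t.st, t.ht) for t in thresholds if t.element == el}
            for el in ("Cd", "As")
        }
        report["quality_classes"] = {
            "rsv_riv": tally_classes(classify_quality(binned, national)),
            "st_ht": tally_classes(classify_quality(binned, regional)),
        }
        _dump(report, out_dir / "evaluation.json")

        _dump(
            {
                "schema_version": SCHEMA_VERSION,
                "version": __version__,
                "seed": config.seed,
                "n": config.generator.n,
                "n_validation": config.n_validation,
                "means_source": config.means_source,
                "plotting_position": config.plotting_position,
                "fix_a_at_100": config.fix_a_at_100,
            },
            out_dir / "run_log.json",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    report["thresholds"] = [t.to_dict() for t in thresholds]
    return report


def worked_examples() -> dict[str, dict]:
    """Recompute the arithmetic identities behind the regional tables.

    Each entry recomputes a published quantity from its published inputs —
    hazard thresholds as MAC × HC95, HT/RIV ratios, and misclassification
    rates from the four-quadrant counts — and reports pass/fail at the
    printed precision.
    """
    limits = load_regulatory_limits()
    out: dict[str, dict] = {}
    for (el, bin_label), hc95 in reference.HC95_INV_BCF.items():
        mac = limits[(el, bin_label)].mac
        _, ht = derive_ht(hc95, mac)
        expected = reference.PUBLISHED_HT[(el, bin_label)]
        decimals = len(str(expected).split(".")[1])
        got = round(ht, decimals)
        out[f"HT_{el}_{bin_label}"] = {
            "computed": got, "expected": expected, "pass": got == expected,
        }
    for bin_label, expected_ratio in (("neutral", 3.2), ("alkaline", 2.5)):
        ht = reference.PUBLISHED_HT[("Cd", bin_label)]
        riv = limits[("Cd", bin_label)].riv
        got = round(ht / riv, 1)
        out[f"HT_over_RIV_Cd_{bin_label}"] = {
            "computed": got, "expected": expected_ratio,
            "pass": got == expected_ratio,
        }
    expected_rates = {"Cd": (66.4, 14.4), "As": (52.0, 17.6)}
    for el, counts in reference.QUADRANT_COUNTS.items():
        n = sum(counts.values())
        fp = round(100.0 * counts["IV"] / n, 1)
        share_i = round(100.0 * counts["I"] / n, 1)
        exp_fp, exp_i = expected_rates[el]
        out[f"false_positive_rate_{el}"] = {
            "computed": fp, "expected": exp_fp, "pass": fp == exp_fp,
        }
        out[f"quadrant_I_share_{el}"] = {
            "computed": share_i, "expected": exp_i, "pass": share_i == exp_i,
        }
    return out
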