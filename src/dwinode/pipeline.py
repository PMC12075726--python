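"""Orchestration: reproducible simulate / fit / study commands.

These functions tie the stages together the way the original analysis
pipeline ran them — simulate inputs, fit voxel-wise parameter maps,
extract ROI means into a cohort table, run the statistical battery —
with every output bundle carrying the seed and a hash of the effective
configuration.  The numbered scripts under ``analysis/`` are thin
drivers over these entry points.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .fitting import FitConfig, PARAMETER_NAMES, ROIMask, extract_roi_means, fit_parameter_maps
from .models import BValueProtocol, CTRWParams, SEMParams
from .stats import (
    METASTATIC_HIGHER,
    SeparationError,
    chi_square_test,
    compare_groups,
    delong_matrix,
    fit_logistic,
    roc_table,
    student_t,
)
from .synthetic import (
    GroupSpec,
    MIAD_CATEGORIES,
    MAAD_CATEGORIES,
    NodePlacement,
    PhantomSpec,
    default_group_specs,
    generate_phantom,
    sample_cohort,
)

__all__ = [
    "config_hash",
    "table1_analogue",
    "table5_analogue",
    "run_study",
    "significance_frequencies",
    "cmd_simulate",
    "cmd_fit",
    "cmd_study",
]


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _check_keys(cfg: dict, allowed: set, where: str) -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys in {where}: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Study over a cohort table


def table1_analogue(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics comparison: chi-square for categorical
    fields (empty categories dropped), pooled t for age."""
    b = cohort[cohort["group"] == "benign"]
    m = cohort[cohort["group"] == "metastatic"]
    rows = []

    def cat_row(field, levels):
        counts = np.array(
            [[int((g[field] == lv).sum()) for lv in levels] for g in (b, m)]
        )
        keep = counts.sum(axis=0) > 0
        res = chi_square_test(counts[:, keep])
        rows.append(
            {
                "characteristic": field,
                "benign": "/".join(str(c) for c in counts[0]),
                "metastatic": "/".join(str(c) for c in counts[1]),
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
            }
        )

    cat_row("sex", ("M", "F"))
    cat_row("miad_category", MIAD_CATEGORIES)
    cat_row("maad_category", MAAD_CATEGORIES)
    cat_row("homogeneous", (True, False))
    cat_row("well_defined", (True, False))
    age = student_t(b["age"], m["age"])
    rows.append(
        {
            "characteristic": "age",
            "benign": f"{b['age'].mean():.1f}±{b['age'].std(ddof=1):.1f}",
            "metastatic": f"{m['age'].mean():.1f}±{m['age'].std(ddof=1):.1f}",
            "test": age.test,
            "statistic": age.statistic,
            "p": age.p,
        }
    )
    return pd.DataFrame(rows).set_index("characteristic")


def table5_analogue(cohort: pd.DataFrame, entry_alpha: float = 0.05) -> dict:
    """Univariable odds ratios per diffusion parameter plus the forward
    stepwise multivariable model over the univariably significant ones."""
    uni_rows = []
    significant = []
    for name in PARAMETER_NAMES:
        try:
            fit = fit_logistic(cohort, [name])
        except SeparationError:
            uni_rows.append({"parameter": name, "odds_ratio": np.nan, "or_ci_low": np.nan,
                             "or_ci_high": np.nan, "p": np.nan, "note": "separation"})
            continue
        row = fit.table.loc[name]
        uni_rows.append(
            {
                "parameter": name,
                "odds_ratio": row["odds_ratio"],
                "or_ci_low": row["or_ci_low"],
                "or_ci_high": row["or_ci_high"],
                "p": row["p"],
                "note": "",
            }
        )
        if row["p"] < entry_alpha:
            significant.append(name)
    uni = pd.DataFrame(uni_rows).set_index("parameter")
    try:
        multi_fit = fit_logistic(cohort, significant, selection="forward_stepwise")
        multi = multi_fit.table
        selected = multi_fit.selected
    except (ValueError, SeparationError):
        multi = pd.DataFrame()
        selected = ()
    return {"univariable": uni, "multivariable": multi, "selected": selected}


def run_study(cohort: pd.DataFrame) -> dict:
    """The full statistical battery on one cohort table."""
    return {
        "table1": table1_analogue(cohort),
        "table3": compare_groups(cohort),
        "table4": roc_table(cohort),
        "table5": table5_analogue(cohort),
        "delong": delong_matrix(cohort),
    }


def significance_frequencies(
    n_replicates: int,
    seed: int,
    benign: GroupSpec | None = None,
    metastatic: GroupSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of replicate cohorts in which each parameter separates
    the groups at ``alpha``, plus the mean-difference sign agreement.

    Replicate k uses seed ``seed + k``; group specs default to the
    published summaries (23 benign / 45 metastatic).
    """
    if benign is None or metastatic is None:
        benign, metastatic = default_group_specs()
    hits = {n: 0 for n in PARAMETER_NAMES}
    sign_ok = {n: 0 for n in PARAMETER_NAMES}
    for k in range(n_replicates):
        cohort = sample_cohort(benign, metastatic, seed + k)
        t3 = compare_groups(cohort)
        for n in PARAMETER_NAMES:
            hits[n] += t3.loc[n, "p"] < alpha
            diff = t3.loc[n, "benign_mean"] - t3.loc[n, "metastatic_mean"]
            expected = -1.0 if n in METASTATIC_HIGHER else 1.0
            sign_ok[n] += np.sign(diff) == expected
    return pd.DataFrame(
        {
            "significant_frequency": {n: hits[n] / n_replicates for n in PARAMETER_NAMES},
            "expected_sign_frequency": {n: sign_ok[n] / n_replicates for n in PARAMETER_NAMES},
        }
    )


# ---------------------------------------------------------------------------
# Commands


def _default_phantom(protocol: BValueProtocol, snr: float, seed: int) -> PhantomSpec:
    nodes = (
        NodePlacement((7.0, 7.0), (3.2, 2.6), 0, "ctrw", CTRWParams(0.78, 0.69, 0.82)),
        NodePlacement((16.0, 16.0), (3.4, 2.8), 0, "ctrw", CTRWParams(0.69, 0.65, 0.89),
                      necrotic_core_frac=0.45),
        NodePlacement((7.0, 17.0), (2.4, 2.4), 0, "sem", SEMParams(0.62, 0.75)),
    )
    return PhantomSpec(shape=(24, 24, 1), protocol=protocol, nodes=nodes, snr=snr, seed=seed)


def cmd_simulate(out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Write a phantom (4-D NIfTI + node/exclusion masks + truth JSON +
    b-value table) and a default cohort CSV under ``out_dir``."""
    config = dict(config or {})
    _check_keys(config, {"snr", "n_benign", "n_metastatic", "correlation"}, "simulate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snr = float(config.get("snr", np.inf))

    protocol = BValueProtocol()
    phantom = generate_phantom(_default_phantom(protocol, snr, seed))
    affine = np.eye(4)
    dio.save_volume4d(phantom["image"], affine, out / "dwi.nii.gz")
    np.savetxt(out / "bvals.txt", 1000.0 * protocol.b[None, :], fmt="%.0f")
    any_mask = np.zeros(phantom["image"].shape[:-1], dtype=np.int16)
    for i, (node_id, m) in enumerate(phantom["masks"].items(), start=1):
        any_mask[m] = i
        excl = phantom["exclusions"][node_id]
        if np.any(excl):
            any_mask[excl] = -i
    dio.save_volume4d(any_mask.astype(np.float32), affine, out / "node_labels.nii.gz")
    (out / "truth.json").write_text(json.dumps({"seed": seed, "snr": str(snr),
                                                "nodes": phantom["truth"]}, indent=2))

    benign, metastatic = default_group_specs(
        n_benign=int(config.get("n_benign", 23)),
        n_metastatic=int(config.get("n_metastatic", 45)),
        correlation=float(config.get("correlation", 0.0)),
    )
    cohort = sample_cohort(benign, metastatic, seed)
    cohort.to_csv(out / "cohort.csv", index=False)

    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def cmd_fit(dwi_path, bval_path, mask_path, out_dir, config: dict | None = None) -> dict:
    """Fit the nine parameter maps for a 4-D DWI volume and extract ROI
    means per labelled node into a cohort-style CSV.

    The mask volume uses positive integer labels for node ROIs and the
    matching negative label for each node's exclusion (necrosis) region.
    """
    config = dict(config or {})
    _check_keys(
        config, {"d_estimation_b_max", "adc_b_max", "refit_d", "n_starts", "seed", "bval_units"},
        "fit",
    )
    protocol = dio.read_bvalues(bval_path, units=config.get("bval_units", "auto"))
    image, affine = dio.load_volume(dwi_path)
    labels, _ = dio.load_volume(mask_path)
    labels = np.round(labels).astype(int)
    if image.ndim != 4 or image.shape[-1] != len(protocol.b_values):
        raise ValueError(
            f"DWI has {image.shape[-1] if image.ndim == 4 else 'non-4D'} volumes "
            f"but the b-value table lists {len(protocol.b_values)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fit_cfg = FitConfig(
        d_estimation_b_max=float(config.get("d_estimation_b_max", 1.0)),
        adc_b_max=config.get("adc_b_max"),
        refit_d=bool(config.get("refit_d", False)),
        n_starts=int(config.get("n_starts", 5)),
        seed=int(config.get("seed", 0)),
    )
    mask = labels != 0
    maps = fit_parameter_maps(image, protocol, mask, fit_cfg, affine)
    for name, pmap in maps.items():
        dio.save_parameter_map(pmap, out / f"{name}.nii.gz")

    records = []
    for label in sorted(set(labels[labels > 0].ravel())):
        roi = ROIMask(labels == label, exclude=labels == -label)
        means = extract_roi_means(maps, roi)
        records.append({"node_id": f"node{label}", **means})
    roi_csv = out / "roi_means.csv"
    pd.DataFrame(records).to_csv(roi_csv, index=False)

    manifest = {
        "seed": fit_cfg.seed,
        "config_hash": config_hash(config),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "n_rois": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def cmd_study(out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Sample a cohort (or read one from ``config['cohort_csv']``), run
    the full statistical battery and write the report bundle."""
    config = dict(config or {})
    _check_keys(
        config,
        {"cohort_csv", "n_benign", "n_metastatic", "correlation", "replicates"},
        "study",
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if "cohort_csv" in config:
        cohort = pd.read_csv(config["cohort_csv"])
    else:
        benign, metastatic = default_group_specs(
            n_benign=int(config.get("n_benign", 23)),
            n_metastatic=int(config.get("n_metastatic", 45)),
            correlation=float(config.get("correlation", 0.0)),
        )
        cohort = sample_cohort(benign, metastatic, seed)
    cohort.to_csv(out / "cohort.csv", index=False)

    study = run_study(cohort)
    study["table1"].to_csv(out / "table1_characteristics.csv")
    study["table3"].to_csv(out / "table3_parameters.csv")
    study["table4"].to_csv(out / "table4_roc.csv")
    study["table5"]["univariable"].to_csv(out / "table5_univariable.csv")
    study["table5"]["multivariable"].to_csv(out / "table5_multivariable.csv")
    study["delong"].to_csv(out / "delong_matrix.csv")

    report = {
        "seed": seed,
        "config_hash": config_hash(config),
        "n_benign": int((cohort["group"] == "benign").sum()),
        "n_metastatic": int((cohort["group"] == "metastatic").sum()),
        "selected_predictors": list(study["table5"]["selected"]),
        "auc": {k: float(v) for k, v in study["table4"]["auc"].items()},
    }
    reps = int(config.get("replicates", 0))
    if reps:
        freq = significance_frequencies(reps, seed)
        freq.to_csv(out / "significance_frequencies.csv")
        report["significance_frequency"] = {
            k: float(v) for k, v in freq["significant_frequency"].items()
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
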