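"""End-to-end orchestration of the discovery and plasma studies.

``run_discovery_study`` wires the synthetic tissue cohort through the
marker-discovery chain (resistant sites -> categorical filter ->
differential shortlist -> panel reduction -> spec site -> coefficient
fit) and persists every intermediate artifact.  ``run_plasma_study``
wires the synthetic plasma cohort through region medians, M scores, the
logistic probability models and the epiLiver classifier.  Every run
writes a manifest (config hash, seed, package version) sufficient to
reproduce the outputs exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, cohortsim, discovery, io, plasma
from .config import RunConfig
from .datatypes import BetaMatrix

logger = logging.getLogger(__name__)


def _write_manifest(cfg: RunConfig, out_dir: Path, stage: str) -> None:
    io.write_json(
        {
            "stage": stage,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.model_dump(),
            "epiliver_version": __version__,
        },
        out_dir / "manifest.json",
    )


def run_discovery_study(cfg: RunConfig) -> dict:
    """Simulate a tissue cohort and recover the marker panel from it."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = cfg.discovery

    matrix, sheet, truth = cohortsim.simulate_tissue_betas(
        cfg.tissue_sim.to_sim_config(), seed=cfg.seed
    )
    io.write_beta_tsv(matrix, out_dir / "betas.tsv")
    io.write_sample_sheet(sheet, out_dir / "samples.csv")
    io.write_truth_json(truth, out_dir / "truth.json")

    groups = sheet.set_index("sample_id")["group"]
    normal_samples = sheet.loc[
        sheet["group"].isin(["blood", "tissue:other"]), "sample_id"
    ].tolist()
    hcc_samples = sheet.loc[sheet["group"] == "HCC", "sample_id"].tolist()
    liver_ctrl = sheet.loc[sheet["group"] == "tissue:liver", "sample_id"].tolist()

    resistant = discovery.resistant_sites(
        matrix.subset_samples(normal_samples), d.max_beta, d.max_median
    )
    logger.info("resistant sites: %d of %d probes", len(resistant), matrix.shape[0])

    case = matrix.subset_samples(hcc_samples)
    ctrl = matrix.subset_samples(liver_ctrl)
    categorical = discovery.categorical_filter(
        case, ctrl, resistant, d.meth_thresh, d.case_frac, d.ctrl_max
    )
    logger.info("categorical survivors: %d (meth>%.2f)", len(categorical), d.meth_thresh)
    ranked = discovery.differential_shortlist(
        case, ctrl, categorical, d.min_abs_delta, d.alpha, d.n_tests, d.top_k
    )
    chain_matrix = matrix.subset_samples(hcc_samples + liver_ctrl)
    chain_labels = np.array([1] * len(hcc_samples) + [0] * len(liver_ctrl))
    panel = discovery.reduce_panel(chain_matrix, chain_labels, ranked, d.target_size)

    # tissue-of-origin search on liver-lineage targets vs non-liver samples,
    # mirroring a training mixture without non-malignant liver controls
    spec_samples = sheet.loc[sheet["group"] != "tissue:liver", "sample_id"].tolist()
    spec_labels = (groups.loc[spec_samples] == "HCC").astype(int).to_numpy()
    _, spec_probe = discovery.spec_site(
        matrix.subset_samples(spec_samples),
        spec_labels,
        d.spec_min_delta,
        d.spec_q_max,
        d.n_tests,
        d.spec_shortlist_size,
    )

    model = discovery.fit_weights(chain_matrix, chain_labels, panel)
    ranked.table.to_csv(out_dir / "shortlist.tsv", sep="\t", index=False)
    io.write_json(
        {
            "detect_cpgs": list(panel.detect_cpgs),
            "spec_cpg": spec_probe,
            "weights": dict(model.weights),
            "intercept": model.intercept,
            "thresholds": {
                "max_beta": d.max_beta,
                "max_median": d.max_median,
                "meth_thresh": d.meth_thresh,
                "min_abs_delta": d.min_abs_delta,
                "n_tests": d.n_tests,
            },
            "selection_rule": "l1-logistic-path; support<=target with AUC>=0.99",
        },
        out_dir / "panel.json",
    )
    _write_manifest(cfg, out_dir, "discovery")
    return {
        "panel": panel,
        "spec_cpg": spec_probe,
        "model": model,
        "truth": truth,
        "resistant": resistant,
        "ranked": ranked,
    }


def run_plasma_study(cfg: RunConfig) -> dict:
    """Simulate a plasma cohort, score it and evaluate the classifier."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    calls, sheet, truth = cohortsim.simulate_plasma_reads(
        cfg.plasma_sim.to_sim_config(), seed=cfg.seed
    )
    sheet = cohortsim.simulate_afp(sheet, seed=cfg.seed + 1)
    io.write_sample_sheet(sheet, out_dir / "samples.csv")
    io.write_truth_json(truth, out_dir / "truth.json")
    io.write_coverage_dir(calls, out_dir / "coverage")

    medians = plasma.region_medians(
        calls, min_reads=cfg.plasma.min_reads, depth_rule=cfg.plasma.depth_rule
    )
    mscores = plasma.m_scores(medians, pseudocount=cfg.plasma.pseudocount)
    medians.to_csv(out_dir / "region_medians.csv")
    mscores.to_csv(out_dir / "mscores.csv")

    qc_fail = mscores.index[~mscores["qc_pass"]].tolist()
    if qc_fail:
        logger.info("excluded %d samples failing coverage QC: %s", len(qc_fail), qc_fail)

    keep = mscores["qc_pass"]
    info = sheet.set_index("sample_id").loc[mscores.index[keep]]
    labels = (info["group"] == "HCC").astype(int).to_numpy()
    md = mscores.loc[keep, "m_detect"].to_numpy()
    ms = mscores.loc[keep, "m_spec"].to_numpy()

    model_d = classify.fit_logistic(md, labels)
    model_s = classify.fit_logistic(ms, labels)
    p_detect = classify.probability(model_d, md)
    p_spec = classify.probability(model_s, ms)
    sum_prob = p_detect + p_spec
    thr = cfg.classify.threshold
    epiliver_calls = np.where(sum_prob > thr, "HCC", "nonHCC")

    probs = pd.DataFrame(
        {
            "p_detect": p_detect,
            "p_spec": p_spec,
            "sum_prob": sum_prob,
            "call": epiliver_calls,
        },
        index=mscores.index[keep],
    )
    probs.index.name = "sample_id"
    probs.to_csv(out_dir / "probabilities.csv")

    report = classify.evaluate(
        epiliver_calls, labels, stages=info["stage"].to_numpy(), scores=sum_prob
    )
    result = {
        "mscores": mscores,
        "probabilities": probs,
        "report": report,
        "models": {"detect": model_d, "spec": model_s},
        "qc_fail": qc_fail,
        "truth": truth,
        "sheet": sheet,
    }
    payload = report.to_dict()
    payload["n_qc_fail"] = len(qc_fail)
    if cfg.classify.use_afp:
        afp_calls = np.array([classify.afp_call(v, cfg.classify.afp_threshold)
                              for v in info["afp_ng_per_ml"]])
        combined = np.array([
            classify.combined_call(e, a) for e, a in zip(epiliver_calls, afp_calls)
        ])
        combined_report = classify.evaluate(
            combined, labels, stages=info["stage"].to_numpy()
        )
        payload["combined_with_afp"] = combined_report.to_dict()
        result["combined_report"] = combined_report
    io.write_json(payload, out_dir / "report.json")
    _write_manifest(cfg, out_dir, "plasma")
    return result
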