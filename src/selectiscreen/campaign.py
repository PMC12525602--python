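"""End-to-end screening campaign: simulate -> reduce -> bench -> screen ->
funnel -> characterize.

``run_campaign`` ties the stages together on synthetic inputs (or
caller-supplied tables), writes per-stage artifacts, and aggregates a
funnel-style report with non-increasing stage counts, the chosen model, and
the characterization fits for the final hits.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import enzym_kinetics, fluorescence, synthetic_data
from .chem_data import DescriptorMatrix, write_table
from .feature_reduction import reduce_matrix
from .model_bench import MODEL_FAMILIES, bench_models, screen_library, split_dataset
from .screening_funnel import FunnelConfig, run_funnel
from .synthetic_data import GeneratorConfig

logger = logging.getLogger(__name__)


@dataclass
class CampaignConfig:
    seed: int = 0
    out_dir: str | None = None
    # stage parameters (module defaults mirrored)
    n_train: int = 300
    n_active: int = 151
    n_library: int = 1000
    k_clusters: int = 30
    test_fraction: float = 0.2
    cv_folds: int = 10
    families: tuple = MODEL_FAMILIES
    screen_threshold: float = 0.5
    funnel: FunnelConfig = field(default_factory=FunnelConfig)
    n_hits: int = 4
    noise_sd: float = 0.3
    assay_noise: float = 0.02


def _characterize_hit(hit_id: str, seed: int) -> dict:
    """Full biophysical characterization of one hit on synthetic assays."""
    dr_table, dr_truth = synthetic_data.gen_dose_response(noise_sd=0.0, seed=seed)
    dr = enzym_kinetics.fit_ic50(
        dr_table.data["concentration"], dr_table.data["inhibition_percent"]
    )
    kin_table, kin_truth = synthetic_data.gen_kinetics(noise_sd=0.0, seed=seed + 1)
    kin = enzym_kinetics.fit_kinetics(kin_table.data)

    q_table, q_truth = synthetic_data.gen_quench(noise_sd=0.0, seed=seed + 2)
    sv_fits = []
    ka_by_t = {}
    for t, grp in q_table.data.groupby("temperature"):
        series = fluorescence.QuenchSeries(
            quencher=grp["quencher"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            temperature=float(t),
            tau0=q_truth["tau0"],
        )
        sv_fits.append(fluorescence.fit_stern_volmer(series))
        ka_by_t[float(t)] = fluorescence.fit_binding_constant(series).ka
    mech = fluorescence.classify_quench_mechanism(sv_fits)
    thermo = fluorescence.fit_vant_hoff(ka_by_t)

    sync_table, sync_truth = synthetic_data.gen_sync_spectra(noise_sd=0.0, seed=seed + 3)
    wavelengths = np.sort(sync_table.data["wavelength"].unique())
    spectra = {
        float(q): grp.sort_values("wavelength")["intensity"].to_numpy()
        for q, grp in sync_table.data.groupby("concentration")
    }
    sync = fluorescence.analyze_sync_spectra(
        fluorescence.SyncSpectrumSeries(
            delta_lambda=sync_truth["delta_lambda"],
            wavelengths=wavelengths,
            spectra=spectra,
        )
    )
    qmax = max(sync.rsqf)
    return {
        "compound_id": hit_id,
        "ic50_uM": dr.ic50 * 1e6,
        "km_mM": kin.km * 1e3,
        "vmax": kin.vmax,
        "ki_mM": kin.ki * 1e3,
        "inhibition_mode": kin.mode,
        "quench_mechanism": mech["mechanism"],
        "ksv_L_per_mol": sv_fits[0].ksv,
        "kq_L_per_mol_s": sv_fits[0].kq,
        "dH_kJ_per_mol": thermo.dh / 1e3,
        "dS_J_per_mol_K": thermo.ds,
        "dG_300K_kJ_per_mol": thermo.dg(300.15) / 1e3,
        "rsqf_max": sync.rsqf[qmax],
        "red_shift_nm": sync.shift[qmax],
    }


def run_campaign(cfg: CampaignConfig) -> dict:
    """Run the full funnel on synthetic data and return the campaign report.

    Stages: generate training set and library -> drop degenerates and reduce
    to ``k_clusters`` representative descriptors -> benchmark the classifier
    families under grid search + stratified CV and rank by TOPSIS -> screen
    the library with the top model -> docking-score selectivity funnel on the
    predicted actives -> pick representatives -> characterize ``n_hits``
    hits with the full assay suite.

    The report is a plain JSON-serializable dict; identical seeds give
    byte-identical reports.
    """
    t0 = time.time()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    gen_cfg = GeneratorConfig(
        seed=cfg.seed,
        n_compounds=cfg.n_train,
        n_active=cfg.n_active,
        noise_sd=cfg.noise_sd,
    )
    train_matrix, train_truth = synthetic_data.gen_descriptor_matrix(gen_cfg)
    logger.info("stage simulate: %d compounds x %d descriptors (%.1fs)",
                train_matrix.n_compounds, train_matrix.n_descriptors, time.time() - t0)

    reduced, reduction = reduce_matrix(train_matrix, k=cfg.k_clusters)
    logger.info("stage reduce: %d -> %d descriptors", train_matrix.n_descriptors,
                reduced.n_descriptors)

    train, test = split_dataset(reduced, test_fraction=cfg.test_fraction, seed=cfg.seed)
    bench = bench_models(train, test, families=cfg.families, folds=cfg.cv_folds, seed=cfg.seed)
    best = bench.best_model
    logger.info("stage bench: best model by TOPSIS = %s", best)

    # library shares the training generator's label model (new compounds)
    lib_cfg = GeneratorConfig(
        seed=cfg.seed + 7919,
        n_compounds=cfg.n_library,
        n_active=max(1, int(round(cfg.n_library * cfg.n_active / cfg.n_train))),
        noise_sd=cfg.noise_sd,
    )
    library, lib_truth = synthetic_data.gen_descriptor_matrix(lib_cfg)
    library = DescriptorMatrix(
        values=library.values.set_axis([f"LIB{i:05d}" for i in range(len(library.values))]),
        families=library.families,
    )
    screened = screen_library(bench.specs[best], library, threshold=cfg.screen_threshold)
    actives = screened.index[screened["label"] == 1].tolist()
    logger.info("stage screen: %d / %d predicted active", len(actives), len(library.values))

    dock_cfg = GeneratorConfig(seed=cfg.seed, selective_fraction=0.05,
                               target_name=cfg.funnel.target_name,
                               offtarget_name=cfg.funnel.offtarget_name)
    dock_table, dock_truth = synthetic_data.gen_docking_scores(dock_cfg, compound_ids=actives)
    desc_actives = library.subset_rows(actives) if actives else None
    funnel_report, representatives = run_funnel(
        dock_table, cfg.funnel, descriptors=desc_actives, seed=cfg.seed
    )
    logger.info("stage funnel: %d -> %d -> %d -> %d", funnel_report.n_input,
                funnel_report.n_target_pass, funnel_report.n_selective,
                funnel_report.n_representatives)

    hits = representatives[: cfg.n_hits]
    characterization = [
        _characterize_hit(hid, seed=cfg.seed + 100 + 10 * i) for i, hid in enumerate(hits)
    ]

    report = {
        "seed": cfg.seed,
        "stage_counts": {
            "train_compounds": train_matrix.n_compounds,
            "descriptors_initial": train_matrix.n_descriptors,
            "descriptors_reduced": reduced.n_descriptors,
            "library_compounds": len(library.values),
            "ml_active": len(actives),
            "target_pass": funnel_report.n_target_pass,
            "selective": funnel_report.n_selective,
            "representatives": funnel_report.n_representatives,
            "characterized_hits": len(characterization),
        },
        "best_model": best,
        "topsis_closeness": bench.topsis.closeness,
        "topsis_ranking": bench.topsis.ranking,
        "test_metrics": {m: v.as_dict() for m, v in bench.metrics.items()},
        "cv_auc": bench.cv_auc,
        "characterization": characterization,
        "selected_features": reduction.selected_features,
    }

    if out_dir:
        write_table(reduced, out_dir / "reduced_matrix.csv")
        write_table(dock_table, out_dir / "docking_scores.csv")
        screened.rename_axis("compound_id").reset_index().to_csv(
            out_dir / "screened_library.csv", index=False
        )
        (out_dir / "campaign_report.json").write_text(json.dumps(report, indent=1, default=float))
        (out_dir / "effective_config.json").write_text(
            json.dumps({k: str(v) for k, v in vars(cfg).items()}, indent=1)
        )
    logger.info("campaign finished in %.1fs", time.time() - t0)
    return report
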