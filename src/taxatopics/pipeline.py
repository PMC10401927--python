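"""End-to-end orchestration: preprocess -> fit -> assign -> match -> DA -> networks.

The run directory persists every intermediate artifact as TSV/YAML/JSON so
each summary number is recomputable from disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    CountTable,
    attach_metadata,
    read_count_table,
    read_metadata,
    write_table,
)
from .diff_abundance import linda_fit
from .lda import LdaModel, fit_lda
from .model_selection import select_topic_number
from .networks import topic_network
from .preprocess import filter_low_prevalence
from .synthetic_data import generate_paired_cohorts, generate_cohort, generate_topics
from .topic_pipeline import assign_reads, match_topics, top_terms, topic_cosine_matrix

__all__ = ["run_pipeline", "DEFAULT_PAIRED_PROFILE"]

log = logging.getLogger("taxatopics")

DEFAULT_PAIRED_PROFILE: dict = {
    "K": 6,
    "V": 150,
    "dominant_per_topic": 10,
    "dominance": 0.9,
    "group_sizes": {"HC": 30, "RRMS": 30},
    "base_alpha": 0.7,
    "disease_topic": 0,
    "disease_group": "RRMS",
    "enrichment": 6.0,
    "epsilon": 0.01,
    "vocab_overlap": 0.97,
    "depth_log_mean": float(np.log(2e4)),
    "depth_log_sd": 0.5,
}


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _simulate_cohorts(sim_cfg: dict, seed: int) -> list[tuple[str, CountTable]]:
    profile = sim_cfg.get("profile", "paired")
    params = dict(DEFAULT_PAIRED_PROFILE)
    params.update({k: v for k, v in sim_cfg.items() if k != "profile"})
    K, V = int(params["K"]), int(params["V"])
    base = np.full(K, float(params["base_alpha"]))
    alpha_by_group = {g: base.copy() for g in params["group_sizes"]}
    dis = params["disease_group"]
    alpha_by_group[dis] = base.copy()
    alpha_by_group[dis][int(params["disease_topic"])] *= float(params["enrichment"])
    beta = generate_topics(
        K, V, int(params["dominant_per_topic"]), float(params["dominance"]), seed=seed
    )
    sizes = {g: int(n) for g, n in params["group_sizes"].items()}
    if profile == "paired":
        paired = generate_paired_cohorts(
            beta,
            alpha_by_group,
            sizes,
            epsilon=float(params["epsilon"]),
            vocab_overlap=float(params["vocab_overlap"]),
            depth_log_mean=float(params["depth_log_mean"]),
            depth_log_sd=float(params["depth_log_sd"]),
            seed=seed,
        )
        return [("cohort_a", paired.table_a), ("cohort_b", paired.table_b)]
    if profile == "single":
        table, _ = generate_cohort(
            beta,
            alpha_by_group,
            sizes,
            depth_log_mean=float(params["depth_log_mean"]),
            depth_log_sd=float(params["depth_log_sd"]),
            seed=seed,
        )
        return [("cohort_a", table)]
    raise ValueError(f"unknown simulation profile {profile!r}")


def _load_cohorts(cfg: dict) -> list[tuple[str, CountTable]]:
    cohorts = []
    group_key = cfg.get("group_key", "group")
    for i, spec in enumerate(cfg["cohorts"]):
        name = spec.get("name", f"cohort_{chr(ord('a') + i)}")
        table = read_count_table(
            spec["counts"],
            format=spec.get("format"),
            orientation=spec.get("orientation", "samples-in-rows"),
        )
        meta = read_metadata(spec["metadata"], format=spec.get("metadata_format"))
        table = attach_metadata(
            table, meta, group_key, drop_uncovered=bool(spec.get("drop_uncovered", False))
        )
        cohorts.append((name, table))
    return cohorts


def _write_model(model: LdaModel, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.beta, index=model.topic_ids, columns=model.vocab).to_csv(
        outdir / "beta.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(
        model.gamma_norm, index=model.sample_ids or None, columns=model.topic_ids
    ).to_csv(outdir / "gamma.tsv", sep="\t", float_format="%.17g")
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "K": int(model.K),
                "alpha": float(model.alpha),
                "eta": float(model.eta),
                "seed": int(model.seed),
                "converged": bool(model.converged),
                "n_iter": int(model.n_iter),
                "final_elbo": float(model.elbo_trace[-1]),
            },
            fh,
        )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full workflow described by ``config``; returns the run dir.

    Stages: preprocess -> (optional) topic-number selection -> LDA fit per
    cohort -> read assignment -> topic DA per cohort -> (two cohorts) topic
    matching -> genus DA within significant matched topics -> networks ->
    summary.  Reruns with the same config and seeds write identical TSVs.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    run_dir = Path(out_dir or cfg.get("out_dir", "taxatopics_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, seed, run_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: dict, seed: int, run_dir: Path) -> Path:
    log.info("taxatopics %s, seed=%d", __version__, seed)
    if "simulate" in cfg:
        cohorts = _simulate_cohorts(cfg["simulate"], seed)
        log.info("simulated %d cohort(s)", len(cohorts))
    elif "cohorts" in cfg:
        cohorts = _load_cohorts(cfg)
    else:
        raise ValueError("config must provide 'cohorts' or 'simulate'")
    if len(cohorts) not in (1, 2):
        raise ValueError("pipeline handles one or two cohorts")

    threshold = float(cfg.get("filter_threshold", 1e-5))
    cosine_threshold = float(cfg.get("cosine_threshold", 0.80))
    p_max = float(cfg.get("p_max", 0.05))
    q_max = float(cfg.get("q_max", 0.25))
    starts = int(cfg.get("starts", 1))
    winsorize_genera = bool(cfg.get("winsorize_genera", True))
    top_rule = cfg.get("top_terms_rule", "cumulative")
    top_cutoff = float(cfg.get("top_terms_cutoff", 0.95))
    lda_settings = dict(cfg.get("lda_settings", {}))

    # ---- preprocess -------------------------------------------------------
    filtered: list[tuple[str, CountTable]] = []
    for name, table in cohorts:
        try:
            ft = filter_low_prevalence(table, threshold)
        except ValueError as exc:
            raise RuntimeError(f"stage preprocess failed on {name}: {exc}") from exc
        (run_dir / name).mkdir(exist_ok=True)
        write_table(ft, run_dir / name / "filtered_counts.tsv")
        pd.DataFrame({"dropped_feature": ft.filter_log}).to_csv(
            run_dir / name / "filter_log.tsv", sep="\t", index=False
        )
        log.info("%s: %d samples x %d genera after filtering (%d dropped)",
                 name, ft.n_samples, ft.n_features, len(ft.filter_log))
        filtered.append((name, ft))

    # ---- choose K ---------------------------------------------------------
    if "k" in cfg:
        chosen_k = int(cfg["k"])
    elif "k_grid" in cfg:
        sel = select_topic_number(
            [t for _, t in filtered], [int(k) for k in cfg["k_grid"]],
            seed=seed, lda_settings=lda_settings,
            table_names=[n for n, _ in filtered],
        )
        sel.curves_frame().to_csv(run_dir / "k_selection.tsv", sep="\t", index=False)
        chosen_k = sel.chosen_k
        log.info("selected K=%d from grid %s", chosen_k, sel.k_grid)
    else:
        raise ValueError("config must set 'k' or 'k_grid'")

    # ---- fit, assign, topic DA -------------------------------------------
    models: list[LdaModel] = []
    topic_da = []
    for name, table in filtered:
        try:
            model = fit_lda(table, K=chosen_k, seed=seed, n_starts=starts, **lda_settings)
        except ValueError as exc:
            raise RuntimeError(f"stage fit failed on {name}: {exc}") from exc
        _write_model(model, run_dir / name)
        assigned = assign_reads(model, table)
        write_table(assigned, run_dir / name / "topic_abundance.tsv")
        da = linda_fit(assigned, winsorize_flag=False, p_max=p_max, q_max=q_max)
        write_table(da, run_dir / name / "da_topics.tsv")
        log.info("%s: fitted K=%d (converged=%s); %d significant topic(s)",
                 name, chosen_k, model.converged, int(da.table["significant"].sum()))
        models.append(model)
        topic_da.append(da)

    # ---- cross-cohort matching -------------------------------------------
    matches = []
    if len(filtered) == 2:
        cos = topic_cosine_matrix(
            models[0].beta, models[0].vocab, models[1].beta, models[1].vocab
        )
        names = [n for n, _ in filtered]
        pd.DataFrame(
            cos,
            index=[f"{names[0]}:{t}" for t in models[0].topic_ids],
            columns=[f"{names[1]}:{t}" for t in models[1].topic_ids],
        ).to_csv(run_dir / "cosine_matrix.tsv", sep="\t", float_format="%.17g")
        matches = match_topics(
            cos, cosine_threshold,
            topics_a=models[0].topic_ids, topics_b=models[1].topic_ids,
        )
        pd.DataFrame([asdict(m) for m in matches]).to_csv(
            run_dir / "matches.tsv", sep="\t", index=False
        )
        log.info("%d topic pair(s) matched at cosine >= %.2f", len(matches), cosine_threshold)
    else:
        log.info("single cohort: matching stage skipped")

    # ---- genus DA within significant topics + networks --------------------
    sig_by_cohort = [set(da.significant_features()) for da in topic_da]
    effects = [dict(zip(da.table["feature"], da.table["effect_log2"])) for da in topic_da]
    genus_da: dict[tuple[str, str], object] = {}
    net_dir = run_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    global_genus_da = bool(cfg.get("global_genus_da", False))
    for ci, (name, table) in enumerate(filtered):
        for topic in sorted(sig_by_cohort[ci]):
            genera = [g for g, _ in top_terms(models[ci], topic, rule=top_rule, cutoff=top_cutoff)]
            sub = table if global_genus_da else table.select_features(genera)
            da = linda_fit(sub, winsorize_flag=winsorize_genera, p_max=p_max, q_max=q_max)
            genus_da[(name, topic)] = da
            write_table(da, run_dir / name / f"da_genera_{topic}.tsv")
            net = topic_network(table, genera, alpha=p_max)
            net.edge_frame().to_csv(
                net_dir / f"{name}_{topic}_edges.tsv", sep="\t", index=False
            )

    # ---- summary -----------------------------------------------------------
    summary = _summarize(
        filtered, models, topic_da, matches, genus_da, effects,
        sig_by_cohort, cosine_threshold, top_rule, top_cutoff, seed,
    )
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("summary: %d validated community type(s)",
             len([m for m in summary["matched_community_types"] if m["validated"]]))
    return run_dir


def _summarize(
    filtered, models, topic_da, matches, genus_da, effects,
    sig_by_cohort, cosine_threshold, top_rule, top_cutoff, seed,
) -> dict:
    names = [n for n, _ in filtered]
    matched = []
    for m in matches:
        sig_a = m.topic_a in sig_by_cohort[0]
        sig_b = m.topic_b in sig_by_cohort[1]
        eff_a = float(effects[0][m.topic_a])
        eff_b = float(effects[1][m.topic_b])
        concordant = eff_a * eff_b > 0
        entry = {
            "topic_a": m.topic_a,
            "topic_b": m.topic_b,
            "cosine": m.cosine,
            "significant_a": bool(sig_a),
            "significant_b": bool(sig_b),
            "effect_a_log2": eff_a,
            "effect_b_log2": eff_b,
            "validated": bool(sig_a and sig_b),
            "concordant_direction": bool(concordant),
            "disease_enriched_both": bool(eff_a > 0 and eff_b > 0),
            "top_genera_a": [g for g, _ in top_terms(models[0], m.topic_a, rule=top_rule, cutoff=top_cutoff)][:15],
            "top_genera_b": [g for g, _ in top_terms(models[1], m.topic_b, rule=top_rule, cutoff=top_cutoff)][:15],
        }
        shared = []
        da_a = genus_da.get((names[0], m.topic_a))
        da_b = genus_da.get((names[1], m.topic_b))
        if da_a is not None and da_b is not None:
            ta, tb = da_a.table.set_index("feature"), da_b.table.set_index("feature")
            for g in set(ta.index) & set(tb.index):
                shared.append(
                    {
                        "genus": g,
                        "effect_a_log2": float(ta.loc[g, "effect_log2"]),
                        "effect_b_log2": float(tb.loc[g, "effect_log2"]),
                        "significant_both": bool(ta.loc[g, "significant"] and tb.loc[g, "significant"]),
                        "direction_concordant": bool(
                            ta.loc[g, "effect_log2"] * tb.loc[g, "effect_log2"] > 0
                        ),
                    }
                )
        entry["shared_genera"] = sorted(shared, key=lambda r: r["genus"])
        matched.append(entry)
    return {
        "version": __version__,
        "seed": seed,
        "cohorts": names,
        "cosine_threshold": cosine_threshold,
        "significant_topics": {n: sorted(s) for n, s in zip(names, sig_by_cohort)},
        "matched_community_types": matched,
    }
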