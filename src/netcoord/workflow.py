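"""End-to-end pipeline: generate networks, synthesize sessions, analyze.

Every stage writes plain-text artifacts (edge lists, CSV tables, JSON
manifests) carrying the configuration hash and all seeds, so a rerun with the
same configuration is reproducible file for file.  The stages are ordinary
functions; the command-line front end in :mod:`netcoord.cli` is a thin
wrapper around them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .config import NETWORK_CLASSES, RunConfig
from .game import PreferenceAssignment
from .networks import Network, read_edge_list, write_edge_list
from .subjects import (
    SessionData,
    generate_experiment,
    read_sessions,
    write_sessions,
)


def _manifest(config: RunConfig, extra: dict) -> dict:
    return {"config": config.to_dict(), "config_hash": config.config_hash(), **extra}


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def generate_networks(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write one edge-list file per network class per session, plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = generate_experiment(config)
    paths, entries = [], []
    for s in sessions:
        path = out / f"network_s{s.session_id:02d}_{s.network_label}.edges"
        write_edge_list(s.network, path)
        paths.append(path)
        entries.append(
            {
                "session_id": s.session_id,
                "network_label": s.network_label,
                "path": path.name,
                "n_nodes": s.network.n_nodes,
                "n_edges": s.network.n_edges,
                "seed": s.network.seed,
            }
        )
    _write_json(_manifest(config, {"networks": entries}), out / "networks_manifest.json")
    return paths


def synthesize(config: RunConfig, out_dir: str | Path) -> list[SessionData]:
    """Generate the synthetic experiment and persist sessions + inputs."""
    out = Path(out_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    (out / "prefs").mkdir(exist_ok=True)
    sessions = generate_experiment(config)
    entries = []
    for s in sessions:
        stem = f"s{s.session_id:02d}_{s.network_label}"
        net_path = out / "networks" / f"{stem}.edges"
        pref_path = out / "prefs" / f"{stem}.csv"
        write_edge_list(s.network, net_path)
        s.prefs.to_csv(pref_path)
        entries.append(
            {
                "session_id": s.session_id,
                "network_label": s.network_label,
                "order_index": s.order_index,
                "network": f"networks/{stem}.edges",
                "prefs": f"prefs/{stem}.csv",
                "seed": s.seed,
            }
        )
    write_sessions(sessions, out / "sessions.csv")
    _write_json(_manifest(config, {"sessions": entries}), out / "sessions_manifest.json")
    return sessions


def load_experiment(out_dir: str | Path) -> tuple[RunConfig, list[SessionData]]:
    """Reload a synthesized experiment from its manifest."""
    out = Path(out_dir)
    manifest = json.loads((out / "sessions_manifest.json").read_text(encoding="utf-8"))
    config = RunConfig(**manifest["config"])
    table = read_sessions(out / "sessions.csv", rounds=config.rounds)
    sessions = []
    for e in manifest["sessions"]:
        network = read_edge_list(out / e["network"], class_label=e["network_label"])
        prefs = PreferenceAssignment.from_csv(out / e["prefs"])
        sub = table[
            (table["session_id"] == e["session_id"])
            & (table["network_label"] == e["network_label"])
        ].reset_index(drop=True)
        sessions.append(
            SessionData(
                e["session_id"],
                e["network_label"],
                network,
                prefs,
                sub,
                e["seed"],
                e.get("order_index", 0),
            )
        )
    return config, sessions


def _analysis_seed(master_seed: int, index: int) -> int:
    return int(np.random.default_rng([master_seed, 7, index]).integers(0, 2**31))


def analyze(
    config: RunConfig, sessions: list[SessionData], out_dir: str | Path | None = None
) -> dict:
    """Run the full statistical battery on an experiment's sessions.

    Per session-network: the median model-data match over ``config.replicates``
    model runs (all rounds and the last ``config.last_k``) and the last-rounds
    heterogeneity.  Across sessions: a one-way ANOVA of heterogeneity by
    network class and a pooled logistic regression of played-preferred
    decisions on degree and even degree.  Returns a summary dict; when
    ``out_dir`` is given, tidy CSVs and a JSON summary are written there.
    """
    rows = []
    for idx, s in enumerate(sessions):
        seed = _analysis_seed(config.seed, idx)
        mm_all = analysis.median_match(
            s.network,
            s.prefs,
            config.scheme,
            s,
            replicates=config.replicates,
            learning_rate=config.learning_rate,
            seed=seed,
        )
        mm_last = analysis.median_match(
            s.network,
            s.prefs,
            config.scheme,
            s,
            replicates=config.replicates,
            rounds_subset=analysis.last_k_rounds(config.rounds, config.last_k),
            learning_rate=config.learning_rate,
            seed=seed,
        )
        het = analysis.heterogeneity(s, last_k=config.last_k)
        rows.append(
            {
                "session_id": s.session_id,
                "network_label": s.network_label,
                "median_r_all": mm_all.median_r,
                "percent_all": mm_all.percent_of_median,
                "median_r_last": mm_last.median_r,
                "percent_last": mm_last.percent_of_median,
                "p_blue": het.p_blue,
                "heterogeneity": het.h,
            }
        )
    per_session = pd.DataFrame(rows)

    h_groups = {
        label: per_session.loc[per_session["network_label"] == label, "heterogeneity"].tolist()
        for label in NETWORK_CLASSES
    }
    anova = analysis.one_way_anova(h_groups)

    decisions = analysis.build_decision_table(sessions)
    coefs = analysis.fit_preference_model(decisions)

    by_class = per_session.groupby("network_label")[
        ["median_r_all", "median_r_last", "heterogeneity"]
    ].mean()
    summary = {
        "per_class": by_class.to_dict(orient="index"),
        "anova": {
            "f": anova.f,
            "df": list(anova.df),
            "p": anova.p,
            "infinite_f": anova.infinite_f,
        },
        "logit": coefs.to_dict(orient="index"),
        "orderings": {
            "match_centralized_gt_random": bool(
                by_class.loc["centralized", "median_r_last"]
                > by_class.loc["random", "median_r_last"]
            ),
            "heterogeneity_clustered_gt_centralized": bool(
                by_class.loc["clustered", "heterogeneity"]
                > by_class.loc["centralized", "heterogeneity"]
            ),
            "degree_coefficient_positive": bool(coefs.loc["degree", "estimate"] > 0),
            "even_degree_coefficient_positive": bool(
                coefs.loc["even_degree", "estimate"] > 0
            ),
        },
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_session.to_csv(out / "per_session.csv", index=False)
        decisions.to_csv(out / "decision_table.csv", index=False)
        coefs.to_csv(out / "logit_coefficients.csv")
        _write_json(_manifest(config, {"summary": summary}), out / "summary.json")
    return summary


def _report_markdown(summary: dict) -> str:
    lines = ["# Synthetic study report", ""]
    lines.append("## Mean per-class statistics")
    lines.append("")
    lines.append("| class | median r (all) | median r (last) | heterogeneity |")
    lines.append("|---|---|---|---|")
    for label, vals in summary["per_class"].items():
        lines.append(
            f"| {label} | {vals['median_r_all']:.3f} | {vals['median_r_last']:.3f} "
            f"| {vals['heterogeneity']:.3f} |"
        )
    a = summary["anova"]
    lines += [
        "",
        f"ANOVA of heterogeneity by class: F({a['df'][0]}, {a['df'][1]}) = "
        f"{a['f']:.2f}, p = {a['p']:.2g}",
        "",
        "## Pooled logistic regression (played preferred)",
        "",
    ]
    for name, row in summary["logit"].items():
        lines.append(
            f"- {name}: {row['estimate']:.4f} (se {row['std_err']:.4f}, "
            f"p {row['p_value']:.3g})"
        )
    lines += ["", "## Qualitative orderings", ""]
    for key, ok in summary["orderings"].items():
        lines.append(f"- {key}: {'yes' if ok else 'NO'}")
    return "\n".join(lines) + "\n"


def reproduce(config: RunConfig, out_dir: str | Path, quick: bool = False) -> dict:
    """Chain generate -> synthesize -> analyze under one master seed."""
    if quick:
        config = config.quick()
    out = Path(out_dir)
    sessions = synthesize(config, out)
    summary = analyze(config, sessions, out)
    (out / "report.md").write_text(_report_markdown(summary), encoding="utf-8")
    return summary
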