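"""End-to-end orchestration: curate -> correlate -> PIC/signal -> WF model.

``run_pipeline`` consumes a :class:`RunConfig` pointing at a rate-estimate
table, a species trait table, an optional mutation-rate table and a rooted
newick tree, and writes curated tables, a correlation table (raw and
phylogenetically independent-contrast variants, with and without named
outlier species), phylogenetic-signal estimates, lifestyle comparisons, a
Wright-Fisher accumulation curve and a JSON summary.  Every statistic carries
its sample size, and all randomness is seeded through the config.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative_stats as cstats
from . import curation, phylo, wright_fisher

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


#: covariates correlated against log10 accumulation rate, with their scale
COVARIATE_SCALES = {
    "genome_size": "linear",
    "gc": "linear",
    "pin_pis": "linear",
    "lab_dt": "log10",
    "rrn_copies": "linear",
    "trna_count": "linear",
}


@dataclass
class RunConfig:
    estimates_path: str
    traits_path: str
    tree_path: str
    outdir: str
    mutation_rates_path: str | None = None
    max_sampling_time: float = 1500.0
    low_variance_sd: float = 0.21
    exclude_species: list[str] = field(default_factory=list)
    outlier_species: list[str] = field(default_factory=list)
    signal_permutations: int = 999
    wf_N: int = 100
    wf_s: float = 0.05
    wf_max_gen_in_N: float = 4.0
    power_alpha: float = 0.05
    power_level: float = 0.95
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        for name in ("estimates_path", "traits_path", "tree_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.mutation_rates_path and not Path(self.mutation_rates_path).exists():
            raise FileNotFoundError(
                f"mutation_rates_path does not exist: {self.mutation_rates_path}"
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj


def _covariate_values(traits: pd.DataFrame, covariate: str) -> pd.Series:
    vals = pd.to_numeric(traits[covariate], errors="coerce")
    if COVARIATE_SCALES.get(covariate) == "log10":
        vals = np.log10(vals.where(vals > 0))
    return vals


def _raw_correlation(merged: pd.DataFrame, covariate: str):
    x = _covariate_values(merged, covariate).to_numpy(dtype=float)
    y = merged["log_rate"].to_numpy(dtype=float)
    return cstats.pearson(x, y)


def _pic_correlation(tree, merged: pd.DataFrame, covariate: str, sd_threshold: float):
    vals = _covariate_values(merged, covariate)
    ok = merged.loc[vals.notna(), "species"].tolist()
    if len(ok) < 4:
        raise ValueError("too few species with data for contrasts")
    sub = tree.extract_tree_with_taxa_labels(ok)
    y_map = dict(zip(merged["species"], merged["log_rate"]))
    x_map = dict(zip(merged["species"], vals))
    cy = phylo.pic(sub, {sp: y_map[sp] for sp in ok})
    cx = phylo.pic(sub, {sp: x_map[sp] for sp in ok})
    keep = cy.expected_sd >= sd_threshold
    removed = int((~keep).sum())
    res = cstats.correlation_through_origin(cx.contrasts[keep], cy.contrasts[keep])
    return res, removed


def run_pipeline(config: RunConfig) -> dict:
    """Run curation, comparative statistics and the WF model; write a report.

    Returns the report bundle as a dict (also serialized to
    ``<outdir>/summary.json`` along with the CSV tables).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _jsonable(dataclasses.asdict(config))}

    # --- curation ------------------------------------------------------------
    try:
        estimates = curation.load_rate_table(config.estimates_path)
        traits = curation.load_trait_table(config.traits_path)
        if config.exclude_species:
            estimates = estimates[~estimates["species"].isin(config.exclude_species)]
            traits = traits[~traits["species"].isin(config.exclude_species)]
        kept, audit = curation.filter_estimates(
            estimates, max_sampling_time=config.max_sampling_time
        )
        means = curation.average_by_species(kept)
        merged = means.merge(traits, on="species", how="inner")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("curation", str(exc)) from exc
    report["curation"] = {
        "n_estimates_in": int(len(estimates)),
        "n_estimates_kept": int(len(kept)),
        "exclusions": [
            {"species": e.species, "reason": e.reason} for e in audit
        ],
        "n_species": int(len(means)),
        "fold_range": curation.fold_range(means["mean_rate"].to_numpy()),
    }
    kept.to_csv(outdir / "curated_estimates.csv", index=False)
    means.to_csv(outdir / "species_means.csv", index=False)

    # --- sampling-time analysis ----------------------------------------------
    try:
        logt = np.log10(kept["sampling_time"].to_numpy(dtype=float))
        logr = curation.log_transform(kept["rate"].to_numpy(dtype=float))
        overall = cstats.pearson(logt, logr)
        counts = kept.groupby("species").size()
        multi = counts[counts >= 2].index.tolist()
        groups = {
            sp: (
                np.log10(kept.loc[kept["species"] == sp, "sampling_time"].to_numpy(float)),
                np.log10(kept.loc[kept["species"] == sp, "rate"].to_numpy(float)),
            )
            for sp in multi
        }
        ancova = cstats.ancova_common_slope(groups) if len(groups) >= 2 else None
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sampling_time", str(exc)) from exc
    report["sampling_time"] = {
        "r": overall.r,
        "p": overall.p,
        "n": overall.n,
        "ancova_slope": None if ancova is None else ancova.common_slope,
        "ancova_p": None if ancova is None else ancova.p,
        "ancova_n_species": None if ancova is None else ancova.n_groups,
    }

    # --- correlation table (raw + PIC, with/without outliers) ------------------
    try:
        tree = phylo.load_tree(config.tree_path)
        rows = []
        variants = {"all": merged}
        if config.outlier_species:
            variants["no_outliers"] = merged[
                ~merged["species"].isin(config.outlier_species)
            ]
        for covariate in COVARIATE_SCALES:
            if covariate not in merged.columns:
                continue
            for variant, data in variants.items():
                try:
                    res = _raw_correlation(data, covariate)
                    rows.append(
                        dict(covariate=covariate, method="raw", variant=variant,
                             r=res.r, p=res.p, n=res.n, removed_contrasts=None)
                    )
                except ValueError:
                    continue
                try:
                    pres, removed = _pic_correlation(
                        tree, data, covariate, config.low_variance_sd
                    )
                    rows.append(
                        dict(covariate=covariate, method="pic", variant=variant,
                             r=pres.r, p=pres.p, n=pres.n,
                             removed_contrasts=removed)
                    )
                except ValueError:
                    pass
        correlations = pd.DataFrame(rows)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("correlations", str(exc)) from exc
    correlations.to_csv(outdir / "correlations.csv", index=False)
    report["correlations"] = _jsonable(correlations.to_dict(orient="records"))

    # --- mutation-rate table ----------------------------------------------------
    if config.mutation_rates_path:
        try:
            mu = pd.read_csv(config.mutation_rates_path)
            res = cstats.pearson(
                np.log10(mu["mutation_rate"].to_numpy(float)),
                np.log10(mu["genome_size"].to_numpy(float)),
            )
            report["mutation_rates"] = {"r": res.r, "p": res.p, "n": res.n}
            if "mutation_rate" in merged.columns:
                both = merged.dropna(subset=["mutation_rate"])
                if len(both) >= 3:
                    overlap = cstats.pearson(
                        np.log10(both["mutation_rate"].to_numpy(float)),
                        both["log_rate"].to_numpy(float),
                    )
                    report["mutation_rates"]["r_vs_accumulation"] = overlap.r
                    report["mutation_rates"]["n_overlap"] = overlap.n
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mutation_rates", str(exc)) from exc

    # --- phylogenetic signal -----------------------------------------------------
    try:
        signal_rows = []
        tree_traits = merged.set_index("species")
        sub = tree.extract_tree_with_taxa_labels(tree_traits.index.tolist())
        for trait_name in ("log_rate", "genome_size", "gc", "pin_pis", "lab_dt"):
            if trait_name not in tree_traits.columns and trait_name != "log_rate":
                continue
            vals = (
                tree_traits["log_rate"]
                if trait_name == "log_rate"
                else _covariate_values(tree_traits.reset_index(), trait_name).set_axis(
                    tree_traits.index
                )
            )
            vals = vals.dropna()
            if len(vals) < 4:
                continue
            sub2 = tree.extract_tree_with_taxa_labels(vals.index.tolist())
            sig = phylo.phylogenetic_signal(
                sub2, vals, n_perm=config.signal_permutations, seed=config.seed
            )
            signal_rows.append(
                dict(trait=trait_name, n=len(vals), **{
                    "lambda": sig.lambda_, "lambda_p": sig.lambda_p,
                    "K": sig.K, "K_p": sig.K_p,
                })
            )
        signal = pd.DataFrame(signal_rows)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("signal", str(exc)) from exc
    signal.to_csv(outdir / "signal.csv", index=False)
    report["signal"] = _jsonable(signal.to_dict(orient="records"))

    # --- lifestyle -----------------------------------------------------------------
    if "lifestyle" in merged.columns:
        try:
            two = merged[merged["lifestyle"].isin(["obligate", "opportunistic"])]
            if two["lifestyle"].nunique() == 2:
                t, p = cstats.group_ttest(
                    two["log_rate"].to_numpy(float), two["lifestyle"].to_numpy()
                )
                entry = {"t": t, "p": p, "n": int(len(two))}
                labels = dict(zip(merged["species"], merged["lifestyle"]))
                in_tree = merged["species"].tolist()
                subt = tree.extract_tree_with_taxa_labels(in_tree)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    pairs = phylo.sister_pairs(subt, labels)
                pairs = [
                    p_ for p_ in pairs
                    if {labels[p_[0]], labels[p_[1]]} == {"obligate", "opportunistic"}
                ]
                if len(pairs) >= 2:
                    rate = dict(zip(merged["species"], merged["log_rate"]))
                    a = [rate[x] if labels[x] == "obligate" else rate[y_] for x, y_ in pairs]
                    b = [rate[y_] if labels[x] == "obligate" else rate[x] for x, y_ in pairs]
                    vals = np.concatenate([a, b])
                    labs = np.array(["obligate"] * len(a) + ["opportunistic"] * len(b))
                    t2, p2 = cstats.group_ttest(vals, labs, paired=True)
                    entry.update(
                        {"paired_t": t2, "paired_p": p2, "n_pairs": len(pairs)}
                    )
                report["lifestyle"] = entry
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("lifestyle", str(exc)) from exc

    # --- multiple regression ----------------------------------------------------
    try:
        predictors = [
            c for c in ("genome_size", "gc", "pin_pis", "lab_dt")
            if c in merged.columns
        ]
        X = pd.DataFrame(
            {c: _covariate_values(merged, c) for c in predictors}
        )
        full = X.notna().all(axis=1)
        if int(full.sum()) > len(predictors) + 2:
            reg = cstats.multiple_regression_standardized(
                X.loc[full], merged.loc[full, "log_rate"].to_numpy(float)
            )
            report["multiple_regression"] = {
                "coefficients": _jsonable(reg.coefficients.to_dict()),
                "p_values": _jsonable(reg.p_values.to_dict()),
                "n": reg.n,
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("multiple_regression", str(exc)) from exc

    # --- power analysis -----------------------------------------------------------
    report["power"] = {
        "n": int(len(means)),
        "alpha": config.power_alpha,
        "power": config.power_level,
        "detectable_r": cstats.detectable_correlation(
            int(len(means)), config.power_alpha, config.power_level
        ),
    }

    # --- Wright-Fisher accumulation curve ------------------------------------------
    try:
        times = wright_fisher.geometric_times(config.wf_N, config.wf_max_gen_in_N)
        curve = wright_fisher.relative_rate_curve(config.wf_N, config.wf_s, times)
        curve.to_frame().to_csv(outdir / "wf_curve.csv", index=False)
        report["wf_model"] = {
            "N": config.wf_N,
            "s": config.wf_s,
            "A_final": float(curve.values[-1]),
            "t_final_in_N": float(curve.times_in_N[-1]),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("wf_model", str(exc)) from exc

    (outdir / "summary.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
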