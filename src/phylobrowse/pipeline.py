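"""End-to-end analysis: cover -> diversity -> NRI -> trait signal -> DBSI.

The pipeline binds the package's stages into one reproducible run driven by
a YAML/dict configuration, producing tidy CSV tables and a JSON report.
Treatment comparison is descriptive (means and percent differences pooled
over plots and years); the tidy tables are the hooks for any external
model fitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derived_int_seed
from .dbsi import mean_dbsi
from .diversity import (
    CoverPanel,
    TREATMENTS,
    read_transect_csv,
    shannon_index,
    species_richness,
)
from .nri import mpd as _mpd, nri_by_treatment_year
from .signal_tests import d_statistic, parsimony_signal_test
from .simulate import SimulationConfig, simulate_dataset
from .trees import PhyloTree, parse_newick

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "AnalysisReport",
    "load_config",
    "run_pipeline",
    "summarize_treatment_differences",
    "read_trait_csv",
    "write_trait_csv",
]


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations (before any computation)."""


# --------------------------------------------------------------------- #
# trait-table I/O (CSV dialect: species,trait_name,state)


def read_trait_csv(path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path)
    for col in ("species", "trait_name", "state"):
        if col not in df.columns:
            raise ConfigError(f"trait CSV missing column {col!r}")
    tables: dict[str, dict[str, str]] = {}
    for trait_name, grp in df.groupby("trait_name"):
        dup = grp["species"].duplicated()
        if dup.any():
            raise ConfigError(
                f"duplicate species in trait {trait_name!r}: "
                f"{sorted(grp.loc[dup, 'species'])}"
            )
        tables[str(trait_name)] = {
            str(r.species).strip(): str(r.state) for r in grp.itertuples(index=False)
        }
    return tables


def write_trait_csv(tables: Mapping[str, Mapping[str, str]], path) -> None:
    rows = [
        {"species": sp, "trait_name": name, "state": state}
        for name, table in sorted(tables.items())
        for sp, state in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["species", "trait_name", "state"]).to_csv(
        path, index=False
    )


# --------------------------------------------------------------------- #
# configuration


_DEFAULTS = {
    "seed": 0,
    "n_perm_nri": 999,
    "n_perm_signal": 1000,
    "missing_species": "error",  # or "drop"
    "signal_tests": [],
    "dbsi": {"plot_threshold": 2, "year_threshold": 2},
}


def load_config(config) -> dict:
    """Normalise and validate a pipeline configuration (fail fast)."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    cfg = {**_DEFAULTS, **config}
    cfg["dbsi"] = {**_DEFAULTS["dbsi"], **(config.get("dbsi") or {})}

    has_inputs = "inputs" in cfg and cfg["inputs"]
    has_synth = "synthetic" in cfg and cfg["synthetic"] is not None
    if has_inputs == has_synth:
        raise ConfigError("configuration needs exactly one of 'inputs' or 'synthetic'")
    if has_inputs:
        inputs = cfg["inputs"]
        if "tree" not in inputs:
            raise ConfigError("inputs.tree (Newick file) is required")
        if ("transects" in inputs) == ("cover" in inputs):
            raise ConfigError("inputs needs exactly one of 'transects' or 'cover'")
        if cfg["signal_tests"] and "traits" not in inputs:
            raise ConfigError("signal_tests requested but inputs.traits is missing")
    for spec in cfg["signal_tests"]:
        if not isinstance(spec, Mapping) or "trait" not in spec or "kind" not in spec:
            raise ConfigError(f"each signal test needs 'trait' and 'kind': {spec!r}")
        if spec["kind"] not in ("binary", "multistate"):
            raise ConfigError(f"signal test kind must be binary/multistate: {spec!r}")
    if cfg["missing_species"] not in ("error", "drop"):
        raise ConfigError("missing_species must be 'error' or 'drop'")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode("utf8")
    ).hexdigest()


# --------------------------------------------------------------------- #
# report


@dataclass
class AnalysisReport:
    """All pipeline outputs; every number traces to one module operation."""

    diversity: pd.DataFrame
    nri: pd.DataFrame
    signal: list[dict]
    dbsi: pd.DataFrame
    treatment_differences: dict
    metadata: dict

    def to_json(self) -> str:
        def frame(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.to_json(orient="records"))

        payload = {
            "diversity": frame(self.diversity),
            "nri": frame(self.nri),
            "signal": self.signal,
            "dbsi": frame(self.dbsi),
            "treatment_differences": self.treatment_differences,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.diversity.to_csv(out / "diversity.csv", index=False)
        self.nri.to_csv(out / "nri.csv", index=False)
        pd.DataFrame(self.signal).to_csv(out / "signal.csv", index=False)
        self.dbsi.to_csv(out / "dbsi.csv", index=False)
        (out / "report.json").write_text(self.to_json())


# --------------------------------------------------------------------- #
# stages


def _load_inputs(cfg: dict):
    if "synthetic" in cfg and cfg["synthetic"] is not None:
        synth = dict(cfg["synthetic"])
        synth.setdefault("master_seed", cfg["seed"])
        if "years" in synth:
            synth["years"] = tuple(synth["years"])
        if "retention" in synth and synth["retention"] is not None:
            synth["retention"] = {int(k): float(v) for k, v in synth["retention"].items()}
        ds = simulate_dataset(SimulationConfig(**synth))
        traits = {
            name: dict(table) for name, table in ds.trait_tables().items()
        }
        return ds.tree, ds.panel, traits
    inputs = cfg["inputs"]
    tree = parse_newick(Path(inputs["tree"]).read_text())
    if "transects" in inputs:
        panel = CoverPanel.from_transect_records(read_transect_csv(inputs["transects"]))
    else:
        panel = CoverPanel.from_csv(inputs["cover"])
    traits = read_trait_csv(inputs["traits"]) if "traits" in inputs else {}
    return tree, panel, traits


def _align_panel_to_tree(panel: CoverPanel, tree: PhyloTree, policy: str) -> CoverPanel:
    missing = sorted(set(panel.species) - set(tree.tip_labels))
    if not missing:
        return panel
    if policy == "error":
        raise ConfigError(f"species in cover but absent from tree: {missing}")
    logger.warning("dropping species absent from tree: %s", missing)
    cover = panel.cover[~panel.cover["species"].isin(missing)]
    return CoverPanel(cover, panel.plots.reset_index())


def _diversity_table(panel: CoverPanel, tree: PhyloTree) -> pd.DataFrame:
    dist = tree.cophenetic_matrix()
    rows = []
    for plot_id in panel.plot_ids():
        for year in panel.years:
            cov = panel.plot_cover(plot_id, year)
            present = cov.index[cov > 0].tolist()
            rows.append(
                {
                    "plot_id": plot_id,
                    "site_id": panel.site_of(plot_id),
                    "treatment": panel.treatment_of(plot_id),
                    "year": year,
                    "richness": species_richness(cov),
                    "shannon": shannon_index(cov) if len(present) else np.nan,
                    "mpd": _mpd(present, dist) if len(present) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _encode_binary(table: Mapping[str, str], trait_name: str) -> dict[str, int]:
    states = sorted(set(table.values()))
    if len(states) != 2:
        raise ConfigError(
            f"binary trait {trait_name!r} must have exactly 2 states, got {states}"
        )
    code = {states[0]: 0, states[1]: 1}
    return {sp: code[st] for sp, st in table.items()}


def _signal_results(
    tree: PhyloTree, traits: Mapping[str, Mapping[str, str]], cfg: dict
) -> list[dict]:
    results = []
    for spec in cfg["signal_tests"]:
        name, kind = spec["trait"], spec["kind"]
        if name not in traits:
            raise ConfigError(f"trait {name!r} not found in trait table")
        table = traits[name]
        test_tree = tree
        missing = sorted(set(tree.tip_labels) - set(table))
        if missing:
            logger.warning("pruning %d tips without %r states", len(missing), name)
            test_tree = tree.prune_to_taxa(set(tree.tip_labels) & set(table))
        seed = derived_int_seed(cfg["seed"], "signal", name)
        if kind == "binary":
            r = d_statistic(
                test_tree, _encode_binary(table, name),
                n_perm=cfg["n_perm_signal"], seed=seed,
            )
        else:
            r = parsimony_signal_test(
                test_tree, {sp: table[sp] for sp in test_tree.tip_labels},
                n_perm=cfg["n_perm_signal"], seed=seed,
            )
        results.append({"trait": name, "kind": kind, **asdict(r)})
    return results


def summarize_treatment_differences(diversity: pd.DataFrame) -> dict:
    """Percent difference of each metric between treatments.

    ``100 * (exclosure_mean - control_mean) / exclosure_mean`` with means
    over plot-years; NaN (flagged) when the exclosure mean is zero.
    """
    out = {}
    for metric in ("richness", "shannon", "mpd"):
        means = {
            t: float(diversity.loc[diversity["treatment"] == t, metric].mean())
            for t in TREATMENTS
        }
        ex, co = means["exclosure"], means["control"]
        undefined = not np.isfinite(ex) or ex == 0
        out[metric] = {
            "exclosure_mean": ex,
            "control_mean": co,
            "percent_reduction": float("nan") if undefined else 100.0 * (ex - co) / ex,
            "undefined": bool(undefined),
        }
    return out


def run_pipeline(config, out_dir=None) -> AnalysisReport:
    """Run the full analysis chain described by ``config``.

    Stages: cover aggregation -> richness/H'/MPD per plot-year ->
    NRI per treatment-year -> trait signal tests -> DBSI.  Deterministic
    for a fixed configuration; all derived seeds are recorded in the
    report metadata.
    """
    cfg = load_config(config)
    tree, panel, traits = _load_inputs(cfg)
    panel = _align_panel_to_tree(panel, tree, cfg["missing_species"])

    diversity = _diversity_table(panel, tree)
    nri_table = nri_by_treatment_year(
        panel, tree, n_perm=cfg["n_perm_nri"], seed=cfg["seed"]
    )
    signal = _signal_results(tree, traits, cfg)
    dbsi_table = mean_dbsi(
        panel,
        plot_threshold=cfg["dbsi"]["plot_threshold"],
        year_threshold=cfg["dbsi"]["year_threshold"],
    )
    report = AnalysisReport(
        diversity=diversity,
        nri=nri_table,
        signal=signal,
        dbsi=dbsi_table,
        treatment_differences=summarize_treatment_differences(diversity),
        metadata={
            "phylobrowse_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": cfg["seed"],
            "n_perm_nri": cfg["n_perm_nri"],
            "n_perm_signal": cfg["n_perm_signal"],
            "config_sha256": _config_hash(cfg),
            "n_species": len(panel.species),
            "years": panel.years,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
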