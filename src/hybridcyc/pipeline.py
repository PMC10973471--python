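"""End-to-end orchestration: synthetic or real inputs through registration,
segmentation, feature extraction, QC, gating, phenotyping and concordance.

Configuration is a YAML file validated into a :class:`PipelineConfig` with
defaults filled; :func:`run_pipeline` executes the stages in study order,
writes per-stage CSV/YAML/JSON/PNG outputs into the output directory, and
returns a manifest recording seeds, per-stage cell counts and output-file
checksums.  All randomness is traceable to the single configured seed, so
two runs with the same config produce byte-identical CSV outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features, gating, phenotyping, registration, segmentation, synthetic
from .concordance import cluster_correlation_matrix, conserved_pairs, export_correlation_heatmap
from .errors import ConfigError
from .layout import RoundLayout, default_layout
from .synthetic import marker_column

_DEFAULTS: dict = {
    "input_mode": "synthetic",  # synthetic | table | images
    "output_dir": "hybridcyc_out",
    "seed": 0,
    "layout": None,  # path to a layout YAML; None -> default 14-marker panel
    "synthetic": {
        "render_images": False,
        "tissue": {"n_cells": 4000, "hybrid_fraction": 0.0083},
        "blood": {"n_cells": 2000, "hybrid_fraction": 0.0015},
        "control": {"n_cells": 500},
        "log_sd": 0.25,
        "image_shape": [256, 256],
    },
    "tables": {"tissue": None, "blood": None, "control": None},
    "images": {"tissue": None, "blood": None},
    "qc": {
        "autofluorescence_quantile": 0.99,
        "autofluorescence_cutoff": None,
        "min_area": 20.0,
        "max_area": None,
        "min_solidity": 0.8,
    },
    "gate": {"rule": "mean_plus_ksd", "k": 3.0, "quantile": 0.995},
    "clustering": {"k_range": [1, 8], "n_restarts": 10, "scope": "pooled_tissue_and_blood"},
    "concordance": {"r_min": 0.7},
}

_VALID_MODES = ("synthetic", "table", "images")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (defaults filled)."""

    settings: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    def __getitem__(self, key):
        return self.settings[key]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=True)

    @property
    def layout(self) -> RoundLayout:
        p = self.settings.get("layout")
        return RoundLayout.from_yaml(p) if p else default_layout()


def _merge_defaults(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_defaults(value, defaults[key], path + key + ".")
        else:
            out[key] = value
    return out


def validate_config(source) -> PipelineConfig:
    """Validate a YAML path or dict into a PipelineConfig.

    Unknown keys, bad enums and invalid ranges raise :class:`ConfigError`
    naming the offending field."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = copy.deepcopy(source or {})
    settings = _merge_defaults(user, _DEFAULTS)

    mode = settings["input_mode"]
    if mode not in _VALID_MODES:
        raise ConfigError(f"input_mode must be one of {_VALID_MODES}, got {mode!r}")
    kr = settings["clustering"]["k_range"]
    if not (isinstance(kr, (list, tuple)) and len(kr) == 2 and kr[1] - kr[0] >= 2):
        raise ConfigError("clustering.k_range must be [lo, hi] spanning at least 3 values")
    if kr[0] < 1:
        raise ConfigError("clustering.k_range lower bound must be >= 1")
    if not (0.0 < settings["qc"]["autofluorescence_quantile"] <= 1.0):
        raise ConfigError("qc.autofluorescence_quantile must lie in (0, 1]")
    if settings["gate"]["rule"] not in gating.GATE_RULES:
        raise ConfigError(f"gate.rule must be one of {gating.GATE_RULES}")
    if mode == "table":
        for key in ("tissue", "blood", "control"):
            p = settings["tables"][key]
            if not p or not Path(p).exists():
                raise ConfigError(f"tables.{key} must point to an existing CSV in table mode")
    if mode == "images":
        for key in ("tissue", "blood"):
            p = settings["images"][key]
            if not p or not Path(p).exists():
                raise ConfigError(f"images.{key} must point to an existing directory in images mode")
    return PipelineConfig(settings)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _phenotype_matrix(table: pd.DataFrame, layout: RoundLayout) -> pd.DataFrame:
    """Marker matrix for phenotyping: each marker read from its configured
    subcellular compartment."""
    cols = {m.name: marker_column(m.name, m.compartment) for m in layout.markers}
    out = pd.DataFrame({name: table[col].to_numpy(dtype=float) for name, col in cols.items()})
    out.index = table.index
    return out


def _specimen_from_images(imgdir, layout, config, specimen_id, specimen_type, manifest):
    stacks, channels = synthetic.read_image_rounds(imgdir)
    aligned, transforms = registration.register_rounds(stacks, channels, layout)
    manifest["stages"].append(
        {
            "stage": f"register:{specimen_id}",
            "transforms": [{"round": t.round_id, "dy": t.dy, "dx": t.dx} for t in transforms],
        }
    )
    ref_round = layout.rounds[0]
    dapi = aligned[ref_round][channels[ref_round].index(layout.nuclear_channel)]
    membrane_marker = "ECAD" if "ECAD" in layout else None
    membrane = None
    if membrane_marker:
        spec = layout[membrane_marker]
        membrane = aligned[spec.round][channels[spec.round].index(spec.channel)]
    masks = segmentation.segment(dapi, membrane)
    manifest["stages"].append({"stage": f"segment:{specimen_id}", "n_cells": masks.n_cells})
    table = features.extract_features(aligned, channels, masks, layout, specimen_id, specimen_type)
    manifest["stages"].append({"stage": f"extract:{specimen_id}", "n_cells": len(table)})
    return table, masks


def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Execute the configured workflow and return the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    s = config.settings
    layout = config.layout
    outdir = Path(s["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(s["seed"])
    manifest: dict = {"started": time.strftime("%Y-%m-%dT%H:%M:%S"), "seed": seed, "stages": []}

    # -- stage 1: obtain single-cell tables --------------------------------
    truths: dict = {}
    masks: dict = {}
    if s["input_mode"] == "synthetic":
        syn = s["synthetic"]
        t_cfg, b_cfg = synthetic.matched_patient_configs(
            tissue_n=syn["tissue"]["n_cells"],
            blood_n=syn["blood"]["n_cells"],
            tissue_hybrid_fraction=syn["tissue"]["hybrid_fraction"],
            blood_hybrid_fraction=syn["blood"]["hybrid_fraction"],
            log_sd=syn["log_sd"],
            seed=seed,
            layout=layout,
        )
        tissue, truths["tissue"] = synthetic.generate_cell_population(t_cfg, layout)
        blood, truths["blood"] = synthetic.generate_cell_population(b_cfg, layout)
        control = synthetic.generate_unstained_control(
            n_cells=syn["control"]["n_cells"], layout=layout, log_sd=syn["log_sd"], seed=seed + 2
        )
        if syn["render_images"]:
            rc = synthetic.RenderConfig(image_shape=tuple(syn["image_shape"]), seed=seed + 3)
            for name, (tab, cfg_seed) in (("tissue", (tissue, seed + 3)), ("blood", (blood, seed + 4))):
                rc_i = synthetic.RenderConfig(image_shape=tuple(syn["image_shape"]), seed=cfg_seed)
                stacks, channels = synthetic.render_image_rounds(tab, truths[name], layout, rc_i)
                imgdir = outdir / f"images_{name}"
                synthetic.write_image_rounds(imgdir, stacks, channels)
            del rc
            tissue_tab, masks["tissue"] = _specimen_from_images(
                outdir / "images_tissue", layout, config, "tissue1", "tissue", manifest
            )
            blood_tab, masks["blood"] = _specimen_from_images(
                outdir / "images_blood", layout, config, "blood1", "blood", manifest
            )
            tissue, blood = tissue_tab, blood_tab
        manifest["stages"].append(
            {"stage": "simulate", "tissue_cells": len(tissue), "blood_cells": len(blood),
             "control_cells": len(control)}
        )
        for name, df in (("tissue_truth", truths["tissue"]), ("blood_truth", truths["blood"])):
            df.to_csv(outdir / f"{name}.csv", index=False)
    elif s["input_mode"] == "table":
        tissue = pd.read_csv(s["tables"]["tissue"])
        blood = pd.read_csv(s["tables"]["blood"])
        control = pd.read_csv(s["tables"]["control"])
        manifest["stages"].append(
            {"stage": "load_tables", "tissue_cells": len(tissue), "blood_cells": len(blood)}
        )
    else:  # images
        tissue, masks["tissue"] = _specimen_from_images(
            s["images"]["tissue"], layout, config, "tissue1", "tissue", manifest
        )
        blood, masks["blood"] = _specimen_from_images(
            s["images"]["blood"], layout, config, "blood1", "blood", manifest
        )
        control = synthetic.generate_unstained_control(layout=layout, seed=seed + 2)

    # -- stage 2: QC -------------------------------------------------------
    qc = s["qc"]
    specimens = {}
    for name, tab in (("tissue", tissue), ("blood", blood)):
        filtered, log = features.run_qc(
            tab,
            masks=masks.get(name),
            autofluorescence_quantile=qc["autofluorescence_quantile"],
            autofluorescence_cutoff=qc["autofluorescence_cutoff"],
            min_area=qc["min_area"],
            max_area=qc["max_area"],
            min_solidity=qc["min_solidity"],
        )
        specimens[name] = filtered
        log.to_csv(outdir / f"qc_log_{name}.csv", index=False)
        manifest["stages"].append(
            {"stage": f"qc:{name}", "rows_in": len(tab), "rows_out": len(filtered),
             "removed": len(tab) - len(filtered)}
        )

    # -- stage 3: gating ---------------------------------------------------
    g = s["gate"]
    gater = gating.MarkerGater(rule=g["rule"], k=g["k"], quantile=g["quantile"]).fit(control)
    gater.thresholds_.to_yaml(outdir / "gate_thresholds.yaml")
    hybrids = {}
    summaries = []
    for name, tab in specimens.items():
        # re-gating a table that already carries calls replaces them
        tab = tab.drop(columns=["is_hybrid", "epithelial_positive_set"], errors="ignore")
        calls = gater.predict(tab)
        hyb = gating.identify_hybrids(calls)
        merged = tab.merge(
            hyb[["cell_id", "is_hybrid", "epithelial_positive_set"]], on="cell_id"
        )
        merged.to_csv(outdir / f"cells_{name}.csv", index=False)
        specimens[name] = merged
        hybrids[name] = merged[merged["is_hybrid"]]
        summaries.append(gating.summarize_counts(hyb, tab))
        manifest["stages"].append(
            {"stage": f"gate:{name}", "n_hybrids": int(hyb["is_hybrid"].sum()), "n_total": len(tab)}
        )
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_json(outdir / "hybrid_summary.json", orient="records", indent=2)

    # -- stage 4: phenotyping ----------------------------------------------
    cl = s["clustering"]
    k_lo, k_hi = cl["k_range"]
    pooled = pd.concat(
        [_phenotype_matrix(hybrids[n], layout) for n in ("tissue", "blood")],
        keys=["tissue", "blood"],
    )
    profiles = {}
    if len(pooled) >= 2:
        normalizer = phenotyping.ZScoreNormalizer().fit(pooled)
        for name in ("tissue", "blood"):
            X = normalizer.transform(_phenotype_matrix(hybrids[name], layout))
            n = len(X)
            if n < 3:
                manifest["stages"].append(
                    {"stage": f"cluster:{name}", "skipped": f"only {n} hybrid cells"}
                )
                continue
            ks = range(k_lo, min(k_hi, n) + 1)
            est = phenotyping.ElbowKMeans(
                k_range=ks, n_restarts=cl["n_restarts"], random_state=seed, compartment=name
            ).fit(X)
            prof, sizes = phenotyping.cluster_profiles(est.model_, X)
            profiles[name] = prof
            prof.assign(n_cells=sizes).to_csv(outdir / f"cluster_profiles_{name}.csv")
            phenotyping.export_heatmap(
                X, est.model_, outdir / f"heatmap_{name}.png", outdir / f"heatmap_{name}.csv"
            )
            manifest["stages"].append(
                {"stage": f"cluster:{name}", "k": est.k_, "wcss": est.wcss_,
                 "cluster_sizes": sizes.to_dict()}
            )
    else:
        manifest["stages"].append({"stage": "cluster", "skipped": "fewer than 2 hybrids pooled"})

    # -- stage 5: concordance ----------------------------------------------
    if "tissue" in profiles and "blood" in profiles:
        matrix = cluster_correlation_matrix(profiles["tissue"], profiles["blood"])
        matrix.to_csv(outdir / "correlation_matrix.csv")
        export_correlation_heatmap(matrix, outdir / "correlation_matrix.png")
        pairs = conserved_pairs(matrix, r_min=s["concordance"]["r_min"])
        pairs.to_csv(outdir / "conserved_pairs.csv", index=False)
        manifest["stages"].append(
            {"stage": "correlate", "max_r": float(np.nanmax(matrix.to_numpy())),
             "n_conserved": len(pairs)}
        )
    else:
        manifest["stages"].append({"stage": "correlate", "skipped": "missing cluster profiles"})

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.csv")) if p.is_file()
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
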