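"""Config validation and three-stage orchestration.

A single YAML config drives simulate -> preprocess -> quantify -> dedup
-> metrics over a set of protocol architectures and replicates. Every
stochastic step receives an explicit seed derived from the config seed,
so re-running an identical config reproduces identical outputs; a run
manifest records the config hash and per-output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dedup as dd
from . import metrics as mx
from . import preprocess as pp
from . import quantify as qt
from . import refio
from . import simulate as sim

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


#: defaults of every tunable, with the convention they trace back to
DEFAULTS: dict[str, Any] = {
    "stage": "spike-in",
    "seed": None,  # mandatory
    "output_dir": "scmirna_out",
    "reference": {
        "path": None,
        "n_seqs": 1006,
        "len_range": [20, 25],
        "gc_profile": [5.5, 16.5],
        "seed": None,  # falls back to the run seed
    },
    "protocols": [
        {
            "name": "SBN",
            "adapter3": sim.DEFAULT_ADAPTER3,
            "adapter5": sim.DEFAULT_ADAPTER5,
            "umi_len": 8,
            "flank4n_len": 0,
            "read_len": 75,
            "replicates": 3,
            "sim": {},
        }
    ],
    "trim": {
        "quality_cutoff": 20,
        "max_error_rate": 0.10,
        "max_rounds": 3,
        "max_n": 2,
        "min_len": 18,
        "dimer_max_len": 3,
    },
    "mapping": {"min_identity": 0.80},
    "class_overlap": 0.90,
    "detection_threshold": 1,
    "subsample": {"enabled": False, "n": 300_000, "seed": 42},
    "dedup": {"group_by_length": True},
    "qc": {"min_molecules": 50},
    "cluster": {
        "n_pcs": 15,
        "umap_neighbors": 15,
        "louvain_resolution": 1.4,
        "snn_k": 20,
        "n_variable_features": 2000,
    },
    "cv_detected_only": False,
}


def _merge(defaults: Any, user: Any, path: str, provenance: dict[str, str]) -> Any:
    if isinstance(defaults, dict):
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        unknown = set(user) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown config keys under {path or 'root'}: {sorted(unknown)}")
        out = {}
        for key, dval in defaults.items():
            sub = f"{path}.{key}" if path else key
            if isinstance(dval, dict):
                out[key] = _merge(dval, user.get(key), sub, provenance)
            elif key in user:
                out[key] = user[key]
                provenance[sub] = "user"
            else:
                out[key] = json.loads(json.dumps(dval))
                provenance[sub] = "default"
        return out
    return user


@dataclass
class PipelineConfig:
    raw: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.raw[key]


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse + validate a YAML config (or an already-parsed mapping),
    filling defaults and recording per-key provenance (user/default).

    A config with no seed anywhere is rejected: every stochastic step
    must be reproducible.
    """
    if isinstance(source, (str, Path)):
        try:
            with open(source) as fh:
                user = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        except OSError as exc:
            raise ConfigError(str(exc)) from exc
    else:
        user = dict(source)
    provenance: dict[str, str] = {}
    protocols = user.pop("protocols", None)
    merged = _merge({k: v for k, v in DEFAULTS.items() if k != "protocols"}, user, "", provenance)
    if protocols is None:
        protocols = json.loads(json.dumps(DEFAULTS["protocols"]))
        provenance["protocols"] = "default"
    else:
        import dataclasses

        sim_fields = {f.name for f in dataclasses.fields(sim.LibrarySimConfig)}
        norm = []
        for i, proto in enumerate(protocols):
            proto = dict(proto)
            sim_cfg = proto.pop("sim", {}) or {}
            unknown = set(sim_cfg) - sim_fields
            if unknown:
                raise ConfigError(
                    f"unknown sim keys in protocols[{i}]: {sorted(unknown)}"
                )
            pdef = {k: v for k, v in DEFAULTS["protocols"][0].items() if k != "sim"}
            merged_proto = _merge(
                json.loads(json.dumps(pdef)), proto, f"protocols[{i}]", provenance
            )
            merged_proto["sim"] = dict(sim_cfg)
            norm.append(merged_proto)
        protocols = norm
    merged["protocols"] = protocols
    if merged.get("seed") is None:
        raise ConfigError("a run seed is mandatory (set 'seed')")
    ref = merged["reference"]
    if ref["path"] is not None and not Path(ref["path"]).exists():
        raise ConfigError(f"reference path does not exist: {ref['path']}")
    if ref["seed"] is None:
        ref["seed"] = merged["seed"]
        provenance["reference.seed"] = "derived"
    for proto in protocols:
        sim.ProtocolArchitecture(
            name=proto["name"],
            adapter3=proto["adapter3"],
            adapter5=proto["adapter5"],
            umi_len=proto["umi_len"],
            flank4n_len=proto["flank4n_len"],
            read_len=proto["read_len"],
        )
        sim.LibrarySimConfig(**{**proto["sim"], "seed": 0})
    return PipelineConfig(raw=merged, provenance=provenance)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_stage(config: PipelineConfig) -> dict[str, Any]:
    """Execute simulate -> preprocess -> quantify -> dedup -> metrics for
    every protocol x replicate in the config; returns the run manifest."""
    cfg = config.raw
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg["seed"])

    step = "reference"
    try:
        ref_cfg = cfg["reference"]
        if ref_cfg["path"]:
            refs = refio.read_fasta_reference(ref_cfg["path"])
        else:
            refs = sim.generate_reference(
                n_seqs=int(ref_cfg["n_seqs"]),
                len_range=tuple(ref_cfg["len_range"]),
                gc_profile=tuple(ref_cfg["gc_profile"]),
                seed=int(ref_cfg["seed"]),
            )
        refio.write_fasta(refs, out_dir / "reference.fasta")

        trim_base = cfg["trim"]
        sample_ids: list[str] = []
        groups: dict[str, str] = {}
        hits_per_sample: dict[str, list[qt.AlignmentHit]] = {}
        qc_rows = []
        umi_tables: dict[str, dd.UMITable] = {}
        index = qt._ReferenceIndex(refs)
        ss = np.random.SeedSequence(master_seed)
        children = iter(ss.generate_state(10_000))

        for proto in cfg["protocols"]:
            arch = sim.ProtocolArchitecture(
                name=proto["name"],
                adapter3=proto["adapter3"],
                adapter5=proto["adapter5"],
                umi_len=proto["umi_len"],
                flank4n_len=proto["flank4n_len"],
                read_len=proto["read_len"],
            )
            bias_seed = int(next(children) % (2**31))
            for rep in range(1, int(proto["replicates"]) + 1):
                sample = f"{proto['name']}_r{rep}"
                sample_ids.append(sample)
                groups[sample] = proto["name"]
                step = f"simulate:{sample}"
                lib_seed = int(next(children) % (2**31))
                lib_cfg = sim.LibrarySimConfig(
                    **{**proto["sim"], "seed": lib_seed, "bias_seed": bias_seed}
                )
                library = sim.simulate_library(refs, arch, lib_cfg, sample_id=sample)
                refio.write_fastq(library.reads, out_dir / f"{sample}.fastq")
                sim.write_ground_truth(
                    library.ground_truth, out_dir / f"{sample}.ground_truth.tsv"
                )

                step = f"preprocess:{sample}"
                reads = library.reads
                if cfg["subsample"]["enabled"]:
                    reads = list(
                        pp.subsample_reads(
                            reads,
                            int(cfg["subsample"]["n"]),
                            int(cfg["subsample"]["seed"]),
                        )
                    )
                trim_cfg = pp.TrimConfig(
                    adapters3=[arch.adapter3],
                    quality_cutoff=int(trim_base["quality_cutoff"]),
                    max_error_rate=float(trim_base["max_error_rate"]),
                    max_rounds=int(trim_base["max_rounds"]),
                    max_n=int(trim_base["max_n"]),
                    min_len=int(trim_base["min_len"]),
                    dimer_max_len=int(trim_base["dimer_max_len"]),
                    flank4n_len=arch.flank4n_len,
                )
                kept, qc = pp.preprocess_reads(reads, trim_cfg, umi_len=arch.umi_len)
                qc_rows.append({"sample": sample, **qc.as_dict()})

                step = f"quantify:{sample}"
                hits = qt.map_to_reference(
                    kept, refs, float(cfg["mapping"]["min_identity"]), index=index
                )
                hits_per_sample[sample] = hits

                step = f"dedup:{sample}"
                if arch.umi_len:
                    umi_tables[sample] = dd.UMITable.from_reads(
                        kept,
                        qt.best_hits(hits),
                        sample,
                        group_by_length=bool(cfg["dedup"]["group_by_length"]),
                    )

        step = "counting"
        matrix = qt.count_features(hits_per_sample, refs.feature_ids)
        matrix.add_layer("rpmm", qt.rpmm_normalize(matrix.layer("raw")))
        if umi_tables:
            mol = pd.DataFrame(
                0, index=matrix.feature_ids, columns=matrix.sample_ids, dtype=np.int64
            )
            for sample, table in umi_tables.items():
                res = dd.dedup_table(table)
                col = dd.molecules_layer(res, matrix.feature_ids, [sample])
                mol[sample] = col[sample]
            matrix.add_layer("molecules", mol)
        matrix.metadata = pd.DataFrame(
            {"protocol": [groups[s] for s in matrix.sample_ids]},
            index=matrix.sample_ids,
        )
        refio.write_count_matrix(matrix, out_dir / "counts")
        pd.DataFrame(qc_rows).to_csv(out_dir / "qc_summary.tsv", sep="\t", index=False)

        step = "metrics"
        raw = matrix.layer("raw")
        rpmm = matrix.layer("rpmm")
        report = mx.MetricsReport()
        for sample in matrix.sample_ids:
            try:
                report.cv_per_sample[sample] = mx.coefficient_of_variation(
                    rpmm[sample],
                    all_feature_ids=matrix.feature_ids,
                    detected_only=bool(cfg["cv_detected_only"]),
                )
            except ValueError:
                report.cv_per_sample[sample] = float("nan")
        if len(matrix.sample_ids) >= 2:
            report.distances = mx.reproducibility_distances(rpmm, groups)
            report.distances.to_csv(out_dir / "distances.tsv", sep="\t", index=False)
        _detected, per_sample, per_feature_rate = qt.detection_calls(
            raw, int(cfg["detection_threshold"])
        )
        report.detected_per_sample = {s: int(v) for s, v in per_sample.items()}
        report.gcontent_rho, report.gcontent_p = mx.gcontent_detection_association(
            refs, per_feature_rate
        )
        if umi_tables:
            per_feat = pd.concat(
                [dd.reads_per_umi(t) for t in umi_tables.values()], ignore_index=True
            )
            summary = dd.reads_per_umi_summary(per_feat)
            summary.to_csv(out_dir / "reads_per_umi.tsv", sep="\t", index=False)
            if len(summary):
                report.reads_per_umi_mean = float(summary["mean_reads_per_umi"].mean())
                report.reads_per_umi_sd = float(summary["mean_reads_per_umi"].std(ddof=1))
        if "molecules" in matrix.layers:
            totals = matrix.layer("molecules").sum(axis=0)
            report.cells_passing_qc = mx.filter_cells(
                totals, int(cfg["qc"]["min_molecules"])
            )
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, default=float)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at step {step}: {exc}") from exc

    step = "manifest"
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    outputs = {
        p.name: _sha256(p) for p in sorted(out_dir.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config_hash": config_hash,
        "stage": cfg["stage"],
        "samples": sample_ids,
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
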