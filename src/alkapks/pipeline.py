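"""Orchestration of the candidate-gene screen and the PKS model report.

``run_screen`` drives the full discovery pipeline on one configuration:
counts + transcripts -> differential expression -> domain hits ->
candidate table -> KS clade placement -> JSON/TSV report, persisting every
intermediate as a flat file and recording seeds and a config hash for
reproducibility.  ``pks_report`` renders the assembly-line simulation for
a configured module architecture.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import expression_screen as es
from . import synthetic_data as sd
from .domain_scan import default_profiles, scan_transcripts, select_candidates
from .ks_phylo import Msa, assign_clade
from .pks_model import (
    AssemblySpec,
    ModuleSpec,
    parse_chain,
    infer_architecture,
    simulate_assembly,
)

__all__ = [
    "RunConfig",
    "run_screen",
    "pks_report",
    "load_assembly_config",
    "load_run_config",
]

log = logging.getLogger("alkapks")


@dataclass
class RunConfig:
    """One screen run: either simulate inputs (default) or read them from
    ``input_dir`` (counts/lengths/samples TSV as written by the
    generators)."""

    output_dir: str = "alkapks_run"
    input_dir: Optional[str] = None
    producer_group: str = sd.PRODUCER_GROUP
    contrast: str = "rest"
    alpha: float = 0.05
    lfc_threshold: float = 2.0
    bootstrap_replicates: int = 200
    n_queries_per_clade: int = 10
    seed: int = 0
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)

    def config_hash(self) -> str:
        # hash the scientific parameters only, not where artifacts land
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage=%s wall=%.2fs", name, t1 - t0)
    return t1


def run_screen(config: RunConfig) -> dict:
    """Execute the screen; returns the report dict (also written to
    ``report.json`` beside the stage artifacts)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- inputs ---------------------------------------------------------
    if config.input_dir is not None:
        cm = es.read_counts(config.input_dir)
        truth = None
        tr_path = Path(config.input_dir) / "transcripts.fasta"
        transcripts = sd.read_fasta(tr_path) if tr_path.exists() else []
    else:
        sim = sd.SimConfig(**{**asdict(config.sim), "seed": config.seed})
        cm, truth = sd.simulate_counts(sim)
        transcripts = sd.simulate_domain_transcripts(truth, seed=config.seed)
        es.write_counts(cm, out)
        sd.write_fasta(transcripts, out / "transcripts.fasta")
        truth.to_json(out / "truth.json")
    t0 = _stage("inputs", t0)

    # --- differential expression ---------------------------------------
    de = es.run_de(
        cm,
        config.producer_group,
        config.contrast,
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
    )
    de.to_csv(out / "de.tsv", sep="\t")
    summary = es.summarize_calls(de)
    t0 = _stage("expression_screen", t0)

    # --- domain scan ----------------------------------------------------
    hits = scan_transcripts(transcripts, default_profiles())
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    candidates = select_candidates(de, hits)
    candidates.to_csv(out / "candidates.tsv", sep="\t")
    assert set(candidates.index) <= set(de.index[de["call"] == "up"]), (
        "candidate table contains genes not called up"
    )
    t0 = _stage("domain_scan", t0)

    # --- KS clade placement --------------------------------------------
    clade_spec = sd.CladeSimSpec()
    records, labels = sd.simulate_clade_sequences(
        clade_spec, seed=config.seed, n_queries_per_clade=config.n_queries_per_clade
    )
    msa = Msa.from_records(records)
    queries = [i for i in msa.ids if i.startswith("q")]
    ref_labels = {i: labels[i] for i in msa.ids if not i.startswith("q")}
    assignments = assign_clade(
        queries, ref_labels, msa,
        b_replicates=config.bootstrap_replicates, seed=config.seed,
    )
    assign_df = pd.DataFrame(
        [(a.query_id, a.clade, a.support, a.monophyletic) for a in assignments],
        columns=["query", "clade", "support", "monophyletic"],
    )
    assign_df.to_csv(out / "clade_assignments.tsv", sep="\t", index=False)
    t0 = _stage("ks_phylo", t0)

    # --- report ---------------------------------------------------------
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "de_summary": summary,
        "dispersion": float(de.attrs["dispersion"]),
        "n_candidates": int(len(candidates)),
        "candidates": candidates.reset_index().to_dict(orient="records"),
        "clade_assignments": assign_df.to_dict(orient="records"),
    }
    if truth is not None:
        planted = set(truth.de_gene_ids)
        called_up = set(de.index[de["call"] == "up"])
        tp = len(planted & called_up)
        report["planted_truth"] = {
            "n_planted": len(planted),
            "recall": tp / len(planted) if planted else None,
            "empirical_fdr": (
                (len(called_up) - tp) / len(called_up) if called_up else 0.0
            ),
            "correct_clade_rate": (
                float(
                    sum(labels[a.query_id] == a.clade for a in assignments)
                    / len(assignments)
                )
                if assignments
                else None
            ),
        }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# --- PKS model front end --------------------------------------------------

def load_assembly_config(path: str | Path) -> AssemblySpec:
    """Assembly spec from YAML: starter/extender carbon counts, ordered
    modules given as domain lists or class names, TE flag, amine token."""
    raw = yaml.safe_load(Path(path).read_text())
    modules = []
    for i, m in enumerate(raw["modules"], start=1):
        if isinstance(m, str):
            modules.append(ModuleSpec.from_class(m, f"Aff-{i}"))
        else:
            modules.append(
                ModuleSpec(
                    name=m.get("name", f"Aff-{i}"),
                    domains=frozenset(m["domains"]),
                )
            )
    return AssemblySpec(
        modules=tuple(modules),
        starter_carbons=int(raw.get("starter_carbons", 2)),
        extender_carbons=int(raw.get("extender_carbons", 2)),
        te_present=bool(raw.get("te_present", True)),
        amine=raw.get("amine"),
    )


def pks_report(spec: AssemblySpec) -> tuple[str, dict]:
    """Human-readable module trace plus a machine-readable product record."""
    product, trace = simulate_assembly(spec)
    text = trace.render() + (
        f"\nproduct: {product.name} ({product.linkage}"
        + (f", {product.amine}" if product.amine else "")
        + ")"
        + (f" = {product.common_name}" if product.common_name else "")
        + (f"\nSMILES: {product.smiles}" if product.smiles else "")
    )
    record = {
        "name": product.name,
        "common_name": product.common_name,
        "n_carbons": product.chain.n_carbons,
        "bonds": [str(b) for b in product.chain.bonds],
        "linkage": product.linkage,
        "amine": product.amine,
        "smiles": product.smiles,
        "intermediates": [str(c) for c in trace.intermediates()],
    }
    return text, record


def design_report(target: str, classes: str = "gd") -> list[list[str]]:
    """Inverse design: module-class sequences producing ``target``."""
    class_map = {"g": "gamma", "d": "delta"}
    allowed = [class_map[c] for c in classes]
    chain = parse_chain(target)
    return [list(seq) for seq in infer_architecture(chain, allowed_classes=allowed)]


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = sd.SimConfig(**raw.pop("sim", {}))
    return RunConfig(sim=sim, **raw)
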