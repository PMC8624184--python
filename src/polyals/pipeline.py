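"""End-to-end orchestration: simulate → barcode → assign → mutations →
primers → qpcr, with a reproducibility manifest.

Every stage writes plain-text outputs (FASTA/CSV/newick/JSON) into the
run directory; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .barcoding import digest, in_silico_pcr
from .homoeolog import (
    CloneSet,
    assign_to_copies,
    cluster_clones,
    derive_anchors,
    trim_anchors,
)
from .io import write_fasta, write_newick
from .mutations import call_tsr, default_reference, mutation_by_copy
from .primers import design_allele_primers, diagnostic_snps, validate_fok1
from .qpcr import expression_frame, expression_table
from .seqcore import Alignment, Sequence
from . import synthdata

log = logging.getLogger("polyals")

STAGES = ("simulate", "barcode", "assign", "mutations", "primers", "qpcr")


@dataclass
class RunConfig:
    """Flat, versionable configuration; every cross-module threshold
    appears here with its default."""

    outdir: str = "polyals-run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # generators
    n_clones_3prime: int = 138
    n_clones_full: int = 30
    error_rate: float = 0.002
    proportions: dict = field(
        default_factory=lambda: dict(synthdata.STUDY_PROPORTIONS)
    )
    # thresholds
    assignment_threshold: float = 0.01
    caps_max_mismatch: int = 0
    allele_max_mismatch: int = 1
    ci_level: float = 0.95
    efficiency: float = 2.0
    calibrators: tuple[str, ...] = ("16S", "161S")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "polyals",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "stages": [],
    }
    state: dict = {}
    for stage in cfg.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            counts = _STAGE_FUNCS[stage](cfg, out, state)
        except Exception as err:                     # noqa: BLE001
            report = {"stage": stage, "error": str(err)}
            (out / "error.json").write_text(json.dumps(report, indent=2))
            raise StageError(stage, err) from err
        log.info("stage %s: %s", stage, counts)
        manifest["stages"].append({"name": stage, **counts})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> dict:
    red, white = synthdata.make_species_models(cfg.seed)
    state["models"] = (red, white)
    templates = [m.als[c] for m in (red, white) for c in sorted(m.als)]
    write_fasta([red.rbcl, white.rbcl] + templates, out / "templates.fa")

    state["panel"] = synthdata.sample_rbcl_panel((red, white), seed=cfg.seed)
    write_fasta(state["panel"], out / "rbcl_panel.fa")

    full_cfg = synthdata.GeneratorConfig(
        seed=cfg.seed + 1, n_clones=cfg.n_clones_full, part="full",
        error_rate=cfg.error_rate, proportions=cfg.proportions,
    )
    state["full_lib"] = synthdata.sample_clone_library((red, white), full_cfg)
    write_fasta(state["full_lib"].clones, out / "clones_full.fa")

    lib3_cfg = synthdata.GeneratorConfig(
        seed=cfg.seed + 2, n_clones=cfg.n_clones_3prime, part="3prime",
        error_rate=cfg.error_rate, proportions=cfg.proportions,
    )
    state["lib3"] = synthdata.sample_clone_library((red, white), lib3_cfg)
    write_fasta(state["lib3"].clones, out / "clones_3prime.fa")

    state["ct"] = synthdata.simulate_qpcr(seed=cfg.seed + 3)
    state["ct"].to_csv(out / "ct_table.csv", index=False)
    return {
        "templates": len(templates) + 2,
        "panel": len(state["panel"]),
        "clones": len(state["full_lib"]) + len(state["lib3"]),
        "ct_rows": len(state["ct"]),
    }


def _stage_barcode(cfg: RunConfig, out: Path, state: dict) -> dict:
    from .barcoding import classify_caps

    red, white = state["models"]
    marker = synthdata.caps_rbcl_marker((red, white))
    state["marker"] = marker
    rows = []
    species_calls = {}
    for sample in state["panel"]:
        call = classify_caps(sample, marker, max_mismatch=cfg.caps_max_mismatch)
        try:
            amp = in_silico_pcr(sample, marker.primers, cfg.caps_max_mismatch)
            frags = digest(amp, marker.enzyme)
            amp_bp = len(amp)
        except Exception:
            frags, amp_bp = [], 0
        rows.append({
            "sample_id": sample.id, "amplicon_bp": amp_bp,
            "fragments": "+".join(map(str, frags)), "call": call,
        })
        species_calls[sample.id] = call
    pd.DataFrame(rows).to_csv(out / "barcode_calls.csv", index=False)
    state["species_calls"] = species_calls
    return {"samples": len(rows),
            "classified": sum(1 for c in species_calls.values()
                              if not c.startswith("unclassified"))}


def _stage_assign(cfg: RunConfig, out: Path, state: dict) -> dict:
    result = cluster_clones(state["full_lib"], cfg.assignment_threshold)
    write_newick(result.tree, out / "clones_full.nwk")
    anchors = derive_anchors(result.clusters, threshold=cfg.assignment_threshold)
    state["anchors"] = anchors
    write_fasta([a.consensus for a in anchors], out / "anchors.fa")

    full_assign = assign_to_copies(state["full_lib"], anchors,
                                   cfg.assignment_threshold)
    state["full_assign"] = full_assign

    trimmed = trim_anchors(anchors, state["lib3"].part)
    assignment = assign_to_copies(state["lib3"], trimmed,
                                  cfg.assignment_threshold)
    state["assignment"] = assignment
    tree3 = cluster_clones(state["lib3"], cfg.assignment_threshold).tree
    write_newick(tree3, out / "clones_3prime.nwk")

    rows = [
        {
            "clone_id": r.clone_id, "population": r.population,
            "species": r.species, "copy": r.copy,
            "distance": round(r.distance, 6), "margin": round(r.margin, 6),
        }
        for r in full_assign.records + assignment.records
    ]
    pd.DataFrame(rows).to_csv(out / "assignments.csv", index=False)
    props = assignment.proportions()
    (out / "proportions.json").write_text(json.dumps(props, indent=2))
    return {"anchors": len(anchors), "assigned": len(assignment.assigned),
            "unassigned": len(assignment.records) - len(assignment.assigned)}


def _stage_mutations(cfg: RunConfig, out: Path, state: dict) -> dict:
    ref = default_reference()
    rows = []
    calls_by_clone = {}
    pops = {}
    for lib, assign in (
        (state["full_lib"], state["full_assign"]),
        (state["lib3"], state["assignment"]),
    ):
        copy_map = assign.as_copy_map()
        for clone in lib:
            calls = call_tsr(clone, ref)
            calls_by_clone[clone.id] = calls
            pops[clone.id] = clone.meta.get("population", "")
            for c in calls:
                rows.append({
                    "clone_id": clone.id,
                    "population": pops[clone.id],
                    "copy": copy_map.get(clone.id, "unassigned"),
                    "position": c.position, "ref_codon": c.ref_codon,
                    "obs_codon": c.obs_codon, "aa_change": c.aa_change,
                    "edits": c.edits, "flag": c.flag,
                })
    pd.DataFrame(rows).to_csv(out / "mutation_calls.csv", index=False)

    copy_map = {
        **state["full_assign"].as_copy_map(),
        **state["assignment"].as_copy_map(),
    }
    table, warns = mutation_by_copy(copy_map, calls_by_clone, pops)
    table.to_csv(out / "mutation_by_copy.csv", index=False)
    if warns:
        (out / "mutation_warnings.txt").write_text("\n".join(warns) + "\n")
    resistant = sum(1 for r in rows if r["flag"] == "known-resistance")
    return {"calls": len(rows), "known_resistance": resistant,
            "warnings": len(warns)}


def _stage_primers(cfg: RunConfig, out: Path, state: dict) -> dict:
    red, white = state["models"]
    rows = [
        Sequence(copy, red.als[copy].residues) for copy in sorted(red.als)
    ]
    aln = Alignment(rows)
    snps = diagnostic_snps(aln, {"ALS1"})
    fwd = next((s for s in snps if s.codon_pos == 590), snps[0] if snps else None)
    rev = next((s for s in snps if s.codon_pos == 621), None)
    if fwd is None or rev is None:
        candidates = [s for s in snps if s.nt_pos > (fwd.nt_pos if fwd else 0)]
        rev = candidates[0] if candidates else None
    if fwd is None or rev is None:
        raise ValueError("no usable diagnostic SNP pair")
    design_t, design_o = design_allele_primers(aln, (fwd, rev), {"ALS1"})

    templates = [m.als[c] for m in (red, white) for c in sorted(m.als)]
    report = validate_fok1((design_t, design_o), templates,
                           max_mismatch=cfg.allele_max_mismatch)
    state["primer_report"] = report
    out_rows = []
    for d in (design_t, design_o):
        out_rows.append({
            "design_id": d.primers.name, "allele_class": d.allele_class,
            "fwd": d.primers.forward, "rev": d.primers.reverse,
            "snp_positions": f"{d.fwd_snp.nt_pos}+{d.rev_snp.nt_pos}",
            "snp_codons": f"{d.fwd_snp.codon_pos}+{d.rev_snp.codon_pos}",
            "introduced_mismatch": f"{d.mismatch_base}@{d.mismatch_nt_pos}",
            "amplicon_bp": ";".join(
                f"{k}={v}" for k, v in sorted(d.amplicon_bp.items())
            ),
        })
    pd.DataFrame(out_rows).to_csv(out / "primer_designs.csv", index=False)
    report.table.to_csv(out / "fok1_validation.csv", index=False)
    return {"designs": 2, "diagnostic_snps": len(snps),
            "fok1_specific": int(report.specific)}


def _stage_qpcr(cfg: RunConfig, out: Path, state: dict) -> dict:
    n_rows = 0
    for cal in cfg.calibrators:
        results = expression_table(
            state["ct"], ref_genes=("Rubisco", "18S"),
            calibrator=(cal, "untreated"),
            efficiency=cfg.efficiency, ci_level=cfg.ci_level,
        )
        frame = expression_frame(results)
        frame.to_csv(out / f"rq_calibrator_{cal}.csv", index=False)
        n_rows += len(frame)
    return {"rq_rows": n_rows, "calibrators": len(cfg.calibrators)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "barcode": _stage_barcode,
    "assign": _stage_assign,
    "mutations": _stage_mutations,
    "primers": _stage_primers,
    "qpcr": _stage_qpcr,
}
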