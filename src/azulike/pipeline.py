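"""End-to-end orchestration of the three screening stages.

Stage order follows the screening workflow: annotation-odds scoring with
selection of score > 0, hydrophobic-percentage window filtering of the
selected sequences, then binding-interface comparison and azurin-like
classification of the survivors.  Each stage writes its TSV report; a run
manifest records the configuration, package version, input checksums and
per-stage status, so two runs on identical inputs produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__, datasets
from . import function_score as fs
from . import interface_analysis as ia
from . import sequence_screen as ss

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "load_config"]

#: distinct exit codes per failing stage
STAGE_EXIT_CODES = {"score": 2, "hpp": 3, "interface": 4}


@dataclass
class PipelineConfig:
    sequences: Path
    annotations: Path
    complexes_dir: Path
    p28_complex: Path
    azurin_complex: Path
    out_dir: Path
    reference_sequences: Path | None = None  # default: bundled azurin + p28
    control_id: str = "azurin"
    tolerance: int = 2
    cutoff: float = 5.0
    receptor_chain: str = "A"
    ligand_chain: str = "B"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        for name in ("sequences", "annotations", "complexes_dir",
                     "p28_complex", "azurin_complex", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.reference_sequences is not None:
            self.reference_sequences = Path(self.reference_sequences)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML pipeline config; keyword overrides win over file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run score -> HPP filter -> interface classification; return the manifest.

    Per-stage TSV reports, the final candidate list and ``manifest.json``
    are written under ``config.out_dir``.  A stage failure writes the
    manifest with a FAILED marker for that stage (partial outputs are
    retained) and raises :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "azulike",
        "version": __version__,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "stages": {},
    }
    for name in ("sequences", "annotations", "p28_complex", "azurin_complex"):
        path = getattr(config, name)
        if path.exists():
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def _fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "FAILED", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise StageError(stage, str(exc)) from exc

    # stage 1: annotation-odds scoring, select score > 0 -------------------
    try:
        annotations = fs.parse_annotation_table(config.annotations)
        refs = fs.reference_categories(annotations, config.control_id)
        candidate_ids = sorted(
            sid for sid in annotations.sequence_ids
            if sid != config.control_id and annotations.is_scorable(sid)
        )
        scores = fs.score_all(annotations, refs, candidate_ids)
        ranked, selected = fs.rank_and_select(scores)
        fs.write_score_report(out / "score_report.tsv", ranked, selected)
        selected_ids = {s.seq_id for s in selected}
    except StageError:
        raise
    except Exception as exc:
        _fail("score", exc)
    manifest["stages"]["score"] = {
        "status": "OK", "n_scored": len(ranked), "n_selected": len(selected_ids),
    }
    logger.info("score: %d scored, %d selected", len(ranked), len(selected_ids))

    # stage 2: hydrophobic-percentage window filter -------------------------
    try:
        records = ss.read_peptide_fasta(config.sequences)
        if not records:
            raise ValueError(f"no sequences in {config.sequences}")
        if config.reference_sequences is not None:
            reference_records = ss.read_peptide_fasta(config.reference_sequences)
        else:
            reference_records = datasets.reference_peptides()
        reference_hpps = [
            ss.hydrophobic_percentage(r.sequence, r.seq_id).hpp
            for r in reference_records
        ]
        window = ss.derive_window(reference_hpps, config.tolerance)
        scored_records = [r for r in records if r.seq_id in selected_ids]
        retained, report = ss.hpp_window_filter(scored_records, window)
        ss.write_hpp_report(out / "hpp_report.tsv", report, window)
    except StageError:
        raise
    except Exception as exc:
        _fail("hpp", exc)
    manifest["stages"]["hpp"] = {
        "status": "OK",
        "window": [window.low, window.high],
        "n_in": len(scored_records),
        "n_retained": len(retained),
    }
    logger.info("hpp: window [%d, %d], %d of %d retained",
                window.low, window.high, len(retained), len(scored_records))

    # stage 3: interface comparison and classification ----------------------
    try:
        params = ia.InterfaceParams(cutoff=config.cutoff)

        def _interface(path: Path) -> ia.BindingInterface:
            model = ia.read_complex_pdb(
                path, config.receptor_chain, config.ligand_chain
            )
            return ia.compute_interface(model, params), model

        p28_iface, _ = _interface(config.p28_complex)
        azurin_iface, _ = _interface(config.azurin_complex)
        rows = []
        final: list[str] = []
        for record in retained:
            pdb_path = Path(config.complexes_dir) / f"{record.seq_id}.pdb"
            if not pdb_path.exists():
                raise FileNotFoundError(f"no docked complex for {record.seq_id}")
            iface, model = _interface(pdb_path)
            if iface.contact_pairs:
                ov_p28 = ia.overlap_with_reference(iface, p28_iface)
                ov_az = ia.overlap_with_reference(iface, azurin_iface)
                comp = ia.interface_composition(iface, model)
                selected_flag = ia.classify_azurin_like(ov_p28, ov_az)
                rows.append({
                    "seq_id": record.seq_id,
                    "size": len(record),
                    "shared_p28": ov_p28.shared_count,
                    "pct_p28": ov_p28.overlap_percent,
                    "shared_azurin": ov_az.shared_count,
                    "pct_azurin": ov_az.overlap_percent,
                    "polar_pct_ligand": comp.ligand_polar,
                    "nonpolar_pct_ligand": comp.ligand_nonpolar,
                    "polar_pct_receptor": comp.receptor_polar,
                    "nonpolar_pct_receptor": comp.receptor_nonpolar,
                    "selected": selected_flag,
                })
            else:
                selected_flag = False
                rows.append({
                    "seq_id": record.seq_id, "size": len(record),
                    "shared_p28": 0, "pct_p28": 0.0,
                    "shared_azurin": 0, "pct_azurin": 0.0,
                    "polar_pct_ligand": 0.0, "nonpolar_pct_ligand": 0.0,
                    "polar_pct_receptor": 0.0, "nonpolar_pct_receptor": 0.0,
                    "selected": False,
                })
            if selected_flag:
                final.append(record.seq_id)
        ia.comparison_report(rows, out / "interface_report.tsv")
        final = sorted(final)
        (out / "final_candidates.txt").write_text("\n".join(final) + "\n")
    except StageError:
        raise
    except Exception as exc:
        _fail("interface", exc)
    manifest["stages"]["interface"] = {
        "status": "OK", "n_compared": len(rows), "n_final": len(final),
    }
    manifest["final_candidates"] = final
    logger.info("interface: %d compared, %d classified azurin-like",
                len(rows), len(final))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
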