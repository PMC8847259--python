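"""End-to-end orchestration: simulate → train → validate → MSI → overlay.

``run_full_workflow`` executes the whole multimodal pipeline on synthetic
phantoms with one master seed and writes every artifact plus a
machine-readable JSON report.  Sub-seeds for each stage are derived
deterministically from the master seed, so an identical configuration yields
an identical report.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import synthetic
from .classify import RdfConfig, ReductionConfig, TissueClassifier, reduce_variables
from .descriptors import build_default_bank, save_bank
from .hyperdata import CLASS_IDS, ValidationError, write_hypercube, write_imzml
from .msi import adduct_mz, extract_ion_image, mass_accuracy_rmse, parse_lipid_shorthand
from .multimodal import overlay_statistics
from .synthetic import (
    DEFAULT_LIPID_PANEL,
    PhantomConfig,
    generate_ftir_phantom,
    generate_msi_phantom,
    generate_reference_collection,
)
from .validation import ValidationConfig

__all__ = ["RunConfig", "run_full_workflow", "StageError"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Merged configuration of every pipeline stage plus the master seed."""

    master_seed: int = 0
    n_sections: int = 5
    per_class: int = 30
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    bank_size: int = 700
    rdf: RdfConfig = field(default_factory=RdfConfig)
    reduction: ReductionConfig | None = None  # None = skip reduction
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    lipid_panel: tuple[synthetic.LipidSpatialSpec, ...] = DEFAULT_LIPID_PANEL
    msi_pixel_size_um: float = 5.0
    ion_tolerance_ppm: float = 2.5
    rmse_window_ppm: float = 4.0
    write_artifacts: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        """Build a RunConfig from a nested plain mapping (e.g. parsed YAML).

        Top-level keys mirror the dataclass fields; ``phantom``, ``rdf``,
        ``reduction`` and ``validation`` accept nested mappings whose keys are
        the respective config fields.
        """
        m = dict(mapping)
        kwargs: dict = {}
        if "phantom" in m:
            kwargs["phantom"] = PhantomConfig(**m.pop("phantom"))
        if "rdf" in m:
            kwargs["rdf"] = RdfConfig(**m.pop("rdf"))
        if "reduction" in m:
            sub = m.pop("reduction")
            kwargs["reduction"] = ReductionConfig(**sub) if sub is not None else None
        if "validation" in m:
            kwargs["validation"] = ValidationConfig(**m.pop("validation"))
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(m) - known
        if unknown:
            raise ValidationError(f"unknown workflow config keys: {sorted(unknown)}")
        kwargs.update(m)
        return cls(**kwargs)

    def sub_seed(self, stage: str) -> int:
        """Stage seed derived deterministically from the master seed."""
        h = int(self.master_seed) & 0xFFFFFFFF
        for ch in stage:
            h = (h * 31 + ord(ch)) & 0xFFFFFFFF
        return h % (2**31 - 1)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_full_workflow(cfg: RunConfig, outdir: str | os.PathLike) -> dict:
    """Run the full multimodal pipeline and return the JSON-able report.

    Stages: phantom simulation, reference sampling, descriptor bank, forest
    training (optionally with variable reduction), Monte Carlo CV,
    whole-image classification, MSI ion images + mass-accuracy RMSE, and
    FTIR→MSI overlay statistics.  Artifacts and ``report.json`` are written
    under ``outdir``.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"master_seed": cfg.master_seed}

    @_stage("simulate")
    def simulate():
        phantoms = []
        for i in range(cfg.n_sections):
            pc = replace(cfg.phantom, seed=cfg.sub_seed(f"phantom-{i}"))
            phantoms.append(generate_ftir_phantom(pc))
        return phantoms

    phantoms = simulate()
    if cfg.write_artifacts:
        for i, (img, _) in enumerate(phantoms):
            write_hypercube(img, os.path.join(outdir, f"section-{i + 1}.h5"))

    @_stage("references")
    def references():
        return generate_reference_collection(
            phantoms, per_class=cfg.per_class, seed=cfg.sub_seed("refs"))

    refs = references()
    report["n_reference_spectra"] = len(refs)

    @_stage("descriptors")
    def descriptors():
        return build_default_bank(refs.axis, cfg.bank_size)

    bank = descriptors()
    report["bank_size"] = bank.n

    if cfg.reduction is not None:
        @_stage("reduce")
        def reduce():
            return reduce_variables(refs, bank, cfg.reduction, cfg.rdf)

        bank, trace = reduce()
        report["reduced_bank_size"] = bank.n
        report["reduction_oob"] = trace.oob_scores()
    if cfg.write_artifacts:
        save_bank(bank, os.path.join(outdir, "bank.tsv"))

    @_stage("train")
    def train():
        model = TissueClassifier(refs, bank,
                                 replace(cfg.rdf, seed=cfg.sub_seed("train")))
        return model, model.fit()

    model, fitres = train()
    report["training_accuracy"] = fitres.training_accuracy

    @_stage("validate")
    def validate():
        vcfg = replace(cfg.validation, seed=cfg.sub_seed("cv"))
        return model.monte_carlo_cv(vcfg)

    cv = validate()
    report["confusion_matrix"] = cv.confusion.counts.tolist()
    report["pooled_predictions"] = cv.confusion.total
    report["total_accuracy"] = cv.overall.total_accuracy
    report["cohens_kappa"] = cv.overall.cohens_kappa
    report["extended_mcc"] = cv.overall.extended_mcc
    report["per_class"] = {
        str(cid): {
            "sensitivity": float(cv.per_class.sensitivity[i]),
            "specificity": float(cv.per_class.specificity[i]),
            "precision": float(cv.per_class.precision[i]),
        }
        for i, cid in enumerate(cv.per_class.class_ids)
    }
    report["n_resampled_splits"] = cv.n_resampled_splits

    @_stage("classify")
    def classify():
        return fitres.classify_image(phantoms[0][0])

    cmap = classify()
    truth0 = phantoms[0][1]
    report["classmap_agreement_with_truth"] = float(
        np.mean(cmap.labels == truth0.class_map.labels))

    @_stage("msi")
    def msi():
        ds = generate_msi_phantom(truth0, list(cfg.lipid_panel),
                                  pixel_size_um=cfg.msi_pixel_size_um,
                                  seed=cfg.sub_seed("msi"))
        ions, accuracy = [], {}
        for sp in cfg.lipid_panel:
            mz = adduct_mz(parse_lipid_shorthand(sp.species_name).formula, sp.adduct)
            ions.append(extract_ion_image(ds, mz, cfg.ion_tolerance_ppm))
            acc = mass_accuracy_rmse(ds, mz, cfg.rmse_window_ppm)
            accuracy[sp.species_name] = {
                "target_mz": mz,
                "rmse_ppm": acc.rmse_ppm if acc.defined else None,
                "n_spectra": acc.n_spectra,
            }
        return ds, ions, accuracy

    ds, ions, accuracy = msi()
    report["mass_accuracy"] = accuracy
    if cfg.write_artifacts:
        write_imzml(ds, os.path.join(outdir, "phantom.imzML"))

    @_stage("overlay")
    def overlay():
        return overlay_statistics(cmap, ions)

    ov = overlay()
    report["overlay"] = {
        f"class{cid}_ion{j}": {"fraction": ov.fraction_inside[(cid, j)],
                               "enrichment": ov.enrichment[(cid, j)]}
        for cid in CLASS_IDS for j in range(len(ions))
    }

    with open(os.path.join(outdir, "report.json"), "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report
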