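"""End-to-end orchestration: candidates -> evidence -> classification.

Prediction is two-stage.  Stage one subtracts parental variants from the
child VCF, leaving candidate sites.  Stage two walks each candidate,
extracts the trio read window from the alignments, and classifies it —
either with the per-variant-type CNN bank or, in rule-based mode, with
the deterministic parental-evidence filter.  Output is a table with one
row per candidate: site key, variant type, DNM probability, label and
filter verdicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import network
from .baseline_filters import (
    FilterThresholds,
    evidence_from_window,
    high_quality_filter,
    inhouse_denovo_filter,
    population_af_prefilter,
)
from .candidates import subtract_inherited
from .encoder import IntensityModel, encode_trio
from .simulate import SimulatedSite
from .trio_io import extract_trio_window, load_trio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_predict", "build_image_dataset", "train_model_bank"]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one prediction run."""

    trio: Dict[str, Dict[str, str]]
    model_dir: Optional[str] = None
    rule_based: bool = False
    threshold: float = 0.5
    mode: Optional[str] = None  # WES | WGS | None (no AF prefilter)
    reference: Optional[str] = None
    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.mode not in (None, "WES", "WGS"):
            raise ValueError("mode must be WES, WGS or unset")
        if not self.rule_based and self.model_dir is None:
            raise ValueError("model_dir required unless rule_based is set")


def _load_model_bank(model_dir: str) -> Dict[str, network.nn.Sequential]:
    bank = {}
    for vtype in ("substitution", "insertion", "deletion"):
        path = Path(model_dir) / f"{vtype}.npz"
        if path.exists():
            model, _ = network.load_checkpoint(path)
            bank[vtype] = model
    if not bank:
        raise FileNotFoundError(f"no model checkpoints found in {model_dir}")
    return bank


def run_predict(
    config: RunConfig,
    population_af: Optional[Dict[Tuple[str, int, str, str], float]] = None,
) -> pd.DataFrame:
    """Run the two-stage prediction for one trio.

    ``population_af`` optionally maps (contig, pos, ref, alt) keys to
    population allele frequencies for the AF-based filters.  A candidate's
    final ``label`` is DNM when its probability clears the threshold
    (inclusive) — rule-based mode emits probability 1.0 or 0.0.
    """
    trio = load_trio(config.trio, reference_path=config.reference)
    child, father, mother = trio
    candidates = subtract_inherited(
        child.variants_path, father.variants_path, mother.variants_path)
    logger.info("%d candidate sites after parental subtraction", len(candidates))

    bank = None if config.rule_based else _load_model_bank(config.model_dir)
    rows = []
    for cand in candidates:
        try:
            window = extract_trio_window(
                trio, cand.contig, cand.position - 1, cand.ref, cand.alt)
        except Exception as exc:
            raise type(exc)(f"{exc} (at {cand.contig}:{cand.position} "
                            f"{cand.ref}>{cand.alt})") from exc
        af = (population_af or {}).get(
            (cand.contig, cand.position, cand.ref, cand.alt))
        evidence = evidence_from_window(window, population_af=af)
        passed, reason = inhouse_denovo_filter(evidence, config.thresholds)
        if config.rule_based:
            p_dnm = 1.0 if passed else 0.0
        else:
            image = encode_trio(window, variant_type=cand.variant_type)
            p_dnm = network.predict(bank, image, cand).p_dnm
        row = {
            "contig": cand.contig,
            "position": cand.position,
            "ref": cand.ref,
            "alt": cand.alt,
            "variant_type": cand.variant_type,
            "p_dnm": p_dnm,
            "label": "DNM" if p_dnm >= config.threshold else "IV",
            "rule_based_pass": passed,
            "rule_based_reason": reason,
            "hq_pass": high_quality_filter(evidence, config.thresholds),
        }
        if config.mode is not None:
            row["af_prefilter_pass"] = population_af_prefilter(
                evidence, config.mode, config.thresholds)
        rows.append(row)
    per_type = pd.Series([r["variant_type"] for r in rows]).value_counts()
    logger.info("candidates per type: %s", per_type.to_dict())
    columns = ["contig", "position", "ref", "alt", "variant_type", "p_dnm",
               "label", "rule_based_pass", "rule_based_reason", "hq_pass"]
    if config.mode is not None:
        columns.append("af_prefilter_pass")
    return pd.DataFrame(rows, columns=columns)


def build_image_dataset(
    sites: Sequence[SimulatedSite],
    intensity_model: IntensityModel = IntensityModel(),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode simulated sites to (images NHWC uint8, labels, variant types)."""
    images = []
    labels = []
    vtypes = []
    for site in sites:
        image = encode_trio(site.window(), intensity_model,
                            variant_type=site.variant_type)
        images.append(image.tensor)
        labels.append(1.0 if site.is_denovo else 0.0)
        vtypes.append(site.variant_type)
    return (np.stack(images), np.asarray(labels, dtype=np.float32),
            np.asarray(vtypes))


def train_model_bank(
    datasets: Dict[str, Tuple[Tuple[np.ndarray, np.ndarray],
                              Tuple[np.ndarray, np.ndarray]]],
    model_config: network.ModelConfig = network.ModelConfig(),
    training_config: network.TrainingConfig = network.TrainingConfig(),
    out_dir: Optional[str] = None,
    seed: int = 0,
) -> Dict[str, Tuple[network.nn.Sequential, network.TrainingHistory]]:
    """Train per-variant-type models; indels warm-start from substitutions.

    ``datasets`` maps variant type to ((x_train, y_train), (x_val, y_val));
    types without data are skipped with a warning.  The substitution model
    trains first with Adam; insertion/deletion models initialise from its
    final weights and train with AdamW.
    """
    results: Dict[str, Tuple[network.nn.Sequential, network.TrainingHistory]] = {}
    sub_weights: Optional[List[np.ndarray]] = None
    order = [t for t in ("substitution", "insertion", "deletion") if t in datasets]
    for vtype in order:
        train_set, val_set = datasets[vtype]
        if len(train_set[0]) == 0:
            logger.warning("no %s training data; skipping that model", vtype)
            continue
        cfg = training_config
        if vtype == "substitution":
            cfg = replace(cfg, optimizer="adam", init_weights=None)
        else:
            cfg = replace(cfg, optimizer="adamw",
                          weight_decay=cfg.weight_decay or 1e-4,
                          init_weights=sub_weights)
        model = network.build_network(model_config, seed=seed)
        model, history = network.train(model, train_set, val_set, cfg)
        if vtype == "substitution":
            sub_weights = model.get_weights()
        results[vtype] = (model, history)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            network.save_checkpoint(model, model_config,
                                    Path(out_dir) / f"{vtype}.npz")
    return results
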