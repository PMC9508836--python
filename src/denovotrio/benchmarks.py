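"""Seeded synthetic benchmark studies of the two calling paths.

Two desk-scale studies quantify recovery on generated trios with known
truth:

* :func:`rule_based_recovery` — writes a trio fixture with planted
  heterozygous de novo and inherited substitutions (clean, well-covered
  parents), runs the full file-based pipeline in rule-based mode, and
  scores the calls against the simulation manifest.

* :func:`cnn_holdout_accuracy` — trains one scaled-down instance of the
  convolutional classifier on encoded synthetic images spanning de novo,
  inherited and artifact classes, and reports accuracy on a held-out
  split.  The default network here uses 3 convolutional layers of 8
  filters (one batch-norm + squeeze-excitation stage) so the study runs
  on a single CPU core in minutes; the architecture family and every
  other mechanism (encoding, augment-free inference, LR schedule,
  best-epoch selection) are identical to the full-size 9-layer/96-filter
  configuration.
"""

from __future__ import annotations

import tempfile
from typing import Dict, Optional

import numpy as np

from . import network, pipeline, simulate
from .evaluate import confusion, metrics

__all__ = ["rule_based_recovery", "cnn_holdout_accuracy"]

# class composition of the CNN training corpus: half de novo, the rest
# inherited variants plus difficult-region-style artifacts
CNN_CLASS_MIX = {
    "denovo": 0.5,
    "inherited_father": 0.2,
    "inherited_mother": 0.2,
    "inherited_both": 0.05,
    "artifact": 0.05,
}


def rule_based_recovery(
    n_sites: int = 200,
    seed: int = 17,
    depth_mean: float = 30.0,
    workdir: Optional[str] = None,
) -> Dict[str, float]:
    """Plant DNMs in a synthetic trio and score the rule-based pipeline.

    Half the sites are clean heterozygous de novo substitutions, half are
    inherited from one parent; parental coverage averages ``depth_mean``.
    Returns sensitivity/precision/accuracy percentages plus the counts.
    """
    mix = {"denovo": 0.5, "inherited_father": 0.25, "inherited_mother": 0.25}
    params = simulate.SimParams(depth_mean=depth_mean)
    sites, reference = simulate.simulate_dataset(
        n_sites, mix, base_params=params, seed=seed,
        reference_length=max(120_000, n_sites * 600))

    def _run(outdir: str) -> Dict[str, float]:
        config = simulate.write_fixture(sites, reference, outdir)
        table = pipeline.run_predict(
            pipeline.RunConfig(trio=config, rule_based=True))
        called = {
            (row["contig"], row["position"], row["ref"], row["alt"])
            for _, row in table.iterrows() if row["label"] == "DNM"
        }
        truth = {s.key: s.is_denovo for s in sites}
        predicted = {k: k in called for k in truth}
        table2 = confusion(truth, predicted)
        m = metrics(table2)
        return {
            "n_sites": n_sites,
            "tp": table2.tp, "fp": table2.fp,
            "tn": table2.tn, "fn": table2.fn,
            "sensitivity_pct": m.sensitivity,
            "precision_pct": m.precision,
            "accuracy_pct": m.accuracy,
        }

    if workdir is not None:
        return _run(workdir)
    with tempfile.TemporaryDirectory() as tmp:
        return _run(tmp)


def cnn_holdout_accuracy(
    n_train: int = 2000,
    n_test: int = 400,
    seed: int = 11,
    max_epochs: int = 6,
    filters: int = 8,
    conv_layers: int = 3,
    learning_rate: float = 3e-3,
) -> Dict[str, object]:
    """Train the scaled-down CNN on synthetic images; report held-out accuracy.

    Simulates ``n_train + n_test`` sites under :data:`CNN_CLASS_MIX`,
    encodes them, trains for at most ``max_epochs`` (best-validation
    weights restored) and evaluates on the held-out ``n_test`` images,
    which double as the validation set for early stopping.
    """
    n_sites = n_train + n_test
    sites, _ = simulate.simulate_dataset(
        n_sites, CNN_CLASS_MIX, seed=seed,
        reference_length=max(200_000, n_sites * 900))
    x, y, _ = pipeline.build_image_dataset(sites)
    x_train, y_train = x[:n_train], y[:n_train]
    x_test, y_test = x[n_train:], y[n_train:]

    mcfg = network.ModelConfig(conv_layers=conv_layers,
                               filters_per_layer=filters,
                               se_block_every=conv_layers)
    tcfg = network.TrainingConfig(
        max_epochs=max_epochs,
        early_stop_patience=max_epochs - 1,
        initial_learning_rate=learning_rate,
        batch_size=32,
        rng_seed=seed % (2 ** 31),
    )
    model = network.build_network(mcfg, seed=seed % (2 ** 31))
    model, history = network.train(model, (x_train, y_train),
                                   (x_test, y_test), tcfg)
    loss, acc = network.evaluate_model(model, x_test, y_test)
    return {
        "n_train": n_train,
        "n_test": n_test,
        "epochs_run": len(history.epochs),
        "best_epoch": history.best_epoch,
        "holdout_loss": loss,
        "holdout_accuracy_pct": 100.0 * acc,
        "history": history,
    }
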