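"""Surrogate regression from structure to oracle score, with atom attribution.

The surrogate ranks unscored molecules between oracle rounds.  The default
backend is a cross-validated ridge regression on Morgan fingerprint bits —
at the few-hundred-molecule training sizes an active-learning round
produces, the linear model's additive inductive bias recovers
fragment-level structure far more efficiently than a neural network, and it
remains competitive at 10k.  A feed-forward ``mlp`` backend is available,
and any regressor honouring the fit/predict contract can be plugged in.
Validation uses the Pearson R² of a seeded 90/10 held-out split.

Atom attribution follows an atom-removal scheme: the contribution of heavy
atom *i* is the prediction of the intact molecule minus the prediction of
the molecule with atom *i* (and its bonds) deleted.  No valence repair is
applied, and all remaining fragments are featurised together, so attribution
mass stays within the featurisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import yaml
from rdkit import Chem
from scipy import sparse
from sklearn.linear_model import RidgeCV
from sklearn.neural_network import MLPRegressor

from .chem_core import MoleculeRecord, ensure_fingerprint, _fp_generator


class InsufficientDataError(ValueError):
    """Raised when fewer than the minimum number of scored records is given."""


MIN_TRAIN_RECORDS = 50


@dataclass(frozen=True)
class SurrogateConfig:
    """Training configuration for the surrogate regressor."""

    n_bits: int = 2048
    radius: int = 2
    backend: str = "ridge"  # "ridge" (cross-validated) or "mlp"
    hidden_layer_sizes: tuple[int, ...] = (64,)
    alpha: float = 1.0  # MLP L2 penalty; the ridge backend selects its own
    batch_size: int = 128
    max_iter: int = 300
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0


def fingerprint_matrix(
    records: Sequence[MoleculeRecord], n_bits: int = 2048, radius: int = 2
) -> sparse.csr_matrix:
    """Sparse 0/1 fingerprint matrix (records × bits)."""
    rows: list[int] = []
    cols: list[int] = []
    for n, rec in enumerate(records):
        fp = ensure_fingerprint(rec, n_bits=n_bits, radius=radius)
        rows.extend([n] * len(fp.on_bits))
        cols.extend(fp.on_bits)
    return sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(records), n_bits)
    )


@dataclass
class AttributionMap:
    """Per-heavy-atom contributions (kcal/mol) to a predicted score."""

    molecule_id: str
    contributions: np.ndarray

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        if not np.all(np.isfinite(self.contributions)):
            raise ValueError("attribution contributions must be finite")


class SurrogateModel:
    """A trained structure→score regressor.

    Use :func:`train_surrogate` to construct; ``predict`` is deterministic
    and batch-size independent.  ``training_meta`` records provenance
    (training size, backend, validation Pearson R²).
    """

    def __init__(self, config: SurrogateConfig, regressor, training_meta: dict):
        self.config = config
        self._regressor = regressor
        self.training_meta = dict(training_meta)

    @property
    def validation_r2(self) -> float:
        return self.training_meta["validation_pearson_r2"]

    def predict(self, records: Sequence[MoleculeRecord], chunk_size: int = 50_000) -> np.ndarray:
        """Predicted scores (kcal/mol), one finite value per record."""
        out = np.empty(len(records))
        for start in range(0, len(records), chunk_size):
            chunk = records[start : start + chunk_size]
            X = fingerprint_matrix(chunk, self.config.n_bits, self.config.radius)
            out[start : start + len(chunk)] = self._predict_matrix(X)
        return out

    def _predict_matrix(self, X: sparse.csr_matrix) -> np.ndarray:
        const = self.training_meta.get("constant_target")
        if const is not None:
            return np.full(X.shape[0], const)
        return np.asarray(self._regressor.predict(X), dtype=float)

    # -- persistence -------------------------------------------------------

    def save(self, prefix: str) -> None:
        """Write a versioned archive: ``<prefix>.yaml`` metadata plus
        ``<prefix>.joblib`` weights."""
        meta = {
            "format_version": 1,
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "n_bits", "radius", "backend", "alpha", "batch_size",
                    "max_iter", "patience", "validation_fraction", "seed")},
                "hidden_layer_sizes": list(self.config.hidden_layer_sizes),
            },
            "training_meta": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.training_meta.items()
            },
        }
        with open(f"{prefix}.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        joblib.dump(self._regressor, f"{prefix}.joblib")

    @classmethod
    def load(cls, prefix: str) -> "SurrogateModel":
        with open(f"{prefix}.yaml") as fh:
            meta = yaml.safe_load(fh)
        cfg = dict(meta["config"])
        cfg["hidden_layer_sizes"] = tuple(cfg["hidden_layer_sizes"])
        config = SurrogateConfig(**cfg)
        regressor = joblib.load(f"{prefix}.joblib")
        return cls(config, regressor, meta["training_meta"])


def _make_regressor(config: SurrogateConfig, n_train: int):
    if config.backend == "ridge":
        # leave-one-out CV over a fixed penalty grid; deterministic
        return RidgeCV(alphas=np.logspace(-1, 2, 16))
    if config.backend != "mlp":
        raise ValueError(f"unknown surrogate backend: {config.backend!r}")
    # early stopping needs a meaningful internal validation split; for small
    # training sets run a fixed number of epochs instead
    early = n_train >= 500
    return MLPRegressor(
        hidden_layer_sizes=config.hidden_layer_sizes,
        alpha=config.alpha,
        batch_size=min(config.batch_size, max(1, n_train)),
        max_iter=config.max_iter if early else 500,
        early_stopping=early,
        n_iter_no_change=config.patience,
        validation_fraction=config.validation_fraction,
        random_state=config.seed,
    )


def train_surrogate(
    records: Sequence[MoleculeRecord],
    scores: Sequence[float],
    config: SurrogateConfig | None = None,
) -> SurrogateModel:
    """Fit the surrogate on scored records and report held-out Pearson R².

    A seeded 90/10 split is made first; the regressor trains on the 90% and
    the reported ``validation_pearson_r2`` is measured on the held-out 10%.
    Constant targets degrade gracefully to a constant predictor with a
    warning.
    """
    config = config or SurrogateConfig()
    scores = np.asarray(scores, dtype=float)
    if len(records) != len(scores):
        raise ValueError("records and scores must have equal length")
    if len(records) < MIN_TRAIN_RECORDS:
        raise InsufficientDataError(
            f"need at least {MIN_TRAIN_RECORDS} scored records, got {len(records)}"
        )
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")

    meta: dict = {"n_train": len(records), "backend": config.backend,
                  "batch_size": config.batch_size, "seed": config.seed}
    if np.ptp(scores) == 0:
        warnings.warn("constant training targets; surrogate predicts the constant")
        meta.update(constant_target=float(scores[0]), validation_pearson_r2=0.0)
        return SurrogateModel(config, None, meta)

    X = fingerprint_matrix(records, config.n_bits, config.radius)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(records))
    n_val = max(1, int(round(config.validation_fraction * len(records))))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    regressor = _make_regressor(config, len(train_idx))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny sets
        regressor.fit(X[train_idx], scores[train_idx])
    pred_val = np.asarray(regressor.predict(X[val_idx]), dtype=float)
    if len(val_idx) >= 2 and np.std(pred_val) > 0 and np.std(scores[val_idx]) > 0:
        r2 = float(np.corrcoef(pred_val, scores[val_idx])[0, 1] ** 2)
    else:
        r2 = 0.0
    meta["validation_pearson_r2"] = r2
    return SurrogateModel(config, regressor, meta)


def predict_scores(model: SurrogateModel, records: Sequence[MoleculeRecord]) -> np.ndarray:
    """Functional alias for :meth:`SurrogateModel.predict`."""
    return model.predict(records)


def _ablated_bitvect(mol: Chem.Mol, atom_idx: int, n_bits: int, radius: int):
    """Fingerprint of the molecule with one heavy atom deleted.

    The atom and its bonds are removed without valence repair; remaining
    fragments are featurised together as one unit.
    """
    rw = Chem.RWMol(mol)
    rw.RemoveAtom(atom_idx)
    frag = rw.GetMol()
    frag.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(frag)
    return _fp_generator(n_bits, radius).GetFingerprint(frag)


def atom_attribution(model: SurrogateModel, record: MoleculeRecord) -> AttributionMap:
    """Atom-removal attribution of the predicted score.

    ``contribution[i] = predict(molecule) − predict(molecule without heavy
    atom i)``; hydrogens are not attributed.  Atom indices follow the
    record's SMILES as parsed.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.id!r}")
    n_heavy = mol.GetNumAtoms()
    if n_heavy < 2:
        raise ValueError("atom attribution needs at least 2 heavy atoms")
    n_bits, radius = model.config.n_bits, model.config.radius
    full_bv = _fp_generator(n_bits, radius).GetFingerprint(mol)
    bitvects = [full_bv] + [_ablated_bitvect(mol, i, n_bits, radius) for i in range(n_heavy)]
    rows, cols = [], []
    for n, bv in enumerate(bitvects):
        on = list(bv.GetOnBits())
        rows.extend([n] * len(on))
        cols.extend(on)
    X = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(bitvects), n_bits))
    preds = model._predict_matrix(X)
    return AttributionMap(molecule_id=record.id, contributions=preds[0] - preds[1:])


def attribution_to_frame(amap: AttributionMap):
    """Attribution as a tidy table (id, atom_index, contribution) for rendering."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": amap.molecule_id,
            "atom_index": np.arange(len(amap.contributions)),
            "contribution": amap.contributions,
        }
    )
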