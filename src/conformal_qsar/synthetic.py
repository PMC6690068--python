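"""Synthetic ChEMBL-like activity tables and class-conditional features.

The generator emits the exact raw-record schema the curation module
consumes, together with a hidden truth table and per-compound feature rows,
so the full pipeline (curation -> features -> both modelling arms ->
evaluation) runs offline with known ground truth.

Class structure of the features: ``n_informative_bits`` fingerprint bits
are Bernoulli(0.5 + s/2) for actives and Bernoulli(0.5 - s/2) for
inactives, where ``s`` is the separability knob (s=0: classes
indistinguishable; s=1: informative bits are deterministic).  The remaining
bits are Bernoulli(0.1) background; six pseudo-physicochemical values come
from class-shifted normals in native-like units.  Measured pChEMBL values
are drawn on the correct side of the family threshold with a safety margin,
and every curation filter (censored '<' rows, duplicate measurements,
flagged duplicates, inconclusive comments, '>' relations, publication
counts) can be exercised at configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import derive_seeds
from .curation import ACTIVE, INACTIVE, MANDATORY_COLUMNS, family_threshold
from .features import N_BITS, PHYSCHEM_NAMES

FAMILIES = ("kinase", "gpcr", "nuclear_receptor", "ion_channel", "other")

# native-unit-like (mean, sd) per pseudo-descriptor; actives are shifted by
# 1.5 * s * sd
_PHYSCHEM_BASE = np.array([350.0, 2.0, 4.0, 5.0, 2.5, 75.0])
_PHYSCHEM_SD = np.array([60.0, 1.2, 1.8, 2.2, 1.2, 25.0])
_COUNT_LIKE = np.array([False, True, True, True, False, False])


class ConfigError(ValueError):
    """Impossible synthetic configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_targets: int = 20
    n_compounds: int = 400
    family_weights: tuple = (0.20, 0.30, 0.10, 0.10, 0.30)  # over FAMILIES
    active_fraction: float = 4.0 / 9.0  # active:inactive ratio 0.8
    separability: float = 0.5
    label_noise: float = 0.0
    n_informative_bits: int = 8
    background_rate: float = 0.1
    n_docs: int = 3
    censored_fraction: float = 0.3
    duplicate_rate: float = 0.05
    flagged_duplicate_rate: float = 0.02
    inconclusive_rate: float = 0.02
    relation_gt_rate: float = 0.02
    pchembl_margin: float = 0.3
    temporal_new_fraction: float = 0.2
    temporal_shift: float = 0.0
    seed: int = 0
    mode: str = "features"  # or "smiles"

    def __post_init__(self):
        for name in (
            "active_fraction", "separability", "label_noise", "background_rate",
            "censored_fraction", "duplicate_rate", "flagged_duplicate_rate",
            "inconclusive_rate", "relation_gt_rate", "temporal_new_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 1 <= self.n_informative_bits <= N_BITS:
            raise ConfigError("n_informative_bits must lie in [1, 2048]")
        if self.mode not in ("features", "smiles"):
            raise ConfigError(f"unknown mode {self.mode!r}")


def generate_features(
    n: int,
    active_fraction: float,
    s: float,
    n_informative_bits: int,
    seed: int,
    background_rate: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled feature rows for one target.

    Returns ``(bits, physchem, labels)``: a (n, 2048) 0/1 matrix, a (n, 6)
    native-unit descriptor block and an object array of 'active'/'inactive'.
    The active count is exactly ``round(n * active_fraction)``.
    """
    n_active = int(round(n * active_fraction))
    if n_active == 0 or n_active == n:
        raise ConfigError(
            f"active_fraction {active_fraction} yields a single-class target of size {n}"
        )
    rng = np.random.default_rng(int(seed))
    labels01 = np.zeros(n, dtype=int)
    labels01[:n_active] = 1
    rng.shuffle(labels01)

    bits = (rng.random((n, N_BITS)) < background_rate).astype(np.uint8)
    p_info = np.where(labels01[:, None] == 1, 0.5 + s / 2.0, 0.5 - s / 2.0)
    bits[:, :n_informative_bits] = (
        rng.random((n, n_informative_bits)) < p_info
    ).astype(np.uint8)

    shift = 1.5 * s * _PHYSCHEM_SD
    means = _PHYSCHEM_BASE + labels01[:, None] * shift
    physchem = rng.normal(means, _PHYSCHEM_SD)
    physchem[:, _COUNT_LIKE] = np.clip(np.round(physchem[:, _COUNT_LIKE]), 0, None)

    labels = np.where(labels01 == 1, ACTIVE, INACTIVE).astype(object)
    return bits, physchem, labels


@dataclass
class SyntheticActivityData:
    """A generated raw activity table with its hidden truth and features."""

    records: pd.DataFrame
    truth: pd.DataFrame  # target_id, compound_id, true_label
    features: dict  # compound_id -> (bits row, physchem row)
    config: SyntheticConfig

    def featurizer(self):
        return make_featurizer(self.features)


def make_featurizer(features: dict):
    """Callable mapping a curated compound table to (bits, physchem) blocks
    by compound-id lookup (the 'precomputed' feature backend)."""

    def _featurize(table: pd.DataFrame):
        rows = [features[c] for c in table["compound_id"]]
        bits = np.vstack([r[0] for r in rows])
        phys = np.vstack([r[1] for r in rows])
        return bits, phys

    return _featurize


def generate_activity_table(config: SyntheticConfig) -> SyntheticActivityData:
    """One raw activity table covering ``n_targets`` targets."""
    target_seeds = derive_seeds(config.seed, config.n_targets, key="target")
    fam_rng = np.random.default_rng(int(derive_seeds(config.seed, 1, key="family")[0]))
    families = fam_rng.choice(
        FAMILIES, size=config.n_targets, p=np.asarray(config.family_weights, dtype=float)
    )
    all_records, all_truth, features = [], [], {}
    for t in range(config.n_targets):
        rec, truth, feats = _one_target(
            f"T{t:03d}", str(families[t]), config, int(target_seeds[t])
        )
        all_records.append(rec)
        all_truth.append(truth)
        features.update(feats)
    records = pd.concat(all_records, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)
    return SyntheticActivityData(records, truth, features, config)


def _one_target(
    target_id: str,
    family: str,
    config: SyntheticConfig,
    seed: int,
    compound_prefix: str = "C",
    separability: float | None = None,
    structure_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    s = config.separability if separability is None else separability
    n = config.n_compounds
    rng = np.random.default_rng(seed)
    bits, physchem, labels = generate_features(
        n, config.active_fraction, s, config.n_informative_bits,
        int(derive_seeds(seed, 1, key="features")[0]), config.background_rate,
    )
    if config.label_noise > 0:
        flip = rng.random(n) < config.label_noise
        labels = np.where(
            flip, np.where(labels == ACTIVE, INACTIVE, ACTIVE), labels
        ).astype(object)

    compound_ids = [f"{target_id}_{compound_prefix}{i:04d}" for i in range(n)]
    smiles = _structures(config, target_id, compound_prefix, n, structure_offset)
    threshold = family_threshold(family)
    margin = config.pchembl_margin
    pchembl = np.where(
        labels == ACTIVE,
        rng.uniform(threshold + margin, threshold + margin + 2.5, n),
        rng.uniform(np.maximum(threshold - margin - 2.5, 0.5), threshold - margin, n),
    )

    doc_ids = [f"{target_id}_DOC{i % max(config.n_docs, 1)}" for i in range(n)]
    censored = (labels == INACTIVE) & (rng.random(n) < config.censored_fraction)

    def row(i, relation, pch, dup=False, comment="", validity=""):
        return {
            "target_id": target_id,
            "family": family,
            "compound_id": compound_ids[i],
            "smiles": smiles[i],
            "relation": relation,
            "pchembl": pch,
            "doc_id": doc_ids[i],
            "src_id": 1,
            "duplicate_flag": dup,
            "data_validity_comment": validity,
            "activity_comment": comment,
        }

    rows = []
    for i in range(n):
        rows.append(row(i, "<" if censored[i] else "=", round(float(pchembl[i]), 3)))
    # repeated measurements of the same compound (jitter inside the margin)
    for i in np.flatnonzero(rng.random(n) < config.duplicate_rate):
        if not censored[i]:
            jitter = rng.uniform(-0.9 * config.pchembl_margin, 0.9 * config.pchembl_margin)
            rows.append(row(i, "=", round(float(pchembl[i] + jitter), 3)))
    # rows that every filter must drop
    for i in np.flatnonzero(rng.random(n) < config.flagged_duplicate_rate):
        rows.append(row(i, "=", round(float(rng.uniform(1, 11)), 3), dup=True))
    for i in np.flatnonzero(rng.random(n) < config.inconclusive_rate):
        rows.append(row(i, "=", round(float(rng.uniform(1, 11)), 3), comment="inconclusive"))
    for i in np.flatnonzero(rng.random(n) < config.relation_gt_rate):
        rows.append(row(i, ">", round(float(rng.uniform(1, 11)), 3)))

    records = pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS))
    truth = pd.DataFrame(
        {"target_id": target_id, "compound_id": compound_ids, "true_label": labels}
    )
    feats = {cid: (bits[i], physchem[i]) for i, cid in enumerate(compound_ids)}
    return records, truth, feats


def _structures(config, target_id, prefix, n, offset):
    if config.mode == "features":
        # opaque tokens; use an identity canonicalizer downstream
        return [f"STRUCT_{target_id}_{prefix}{i + offset:04d}" for i in range(n)]
    from .smiles_fixtures import distinct_canonical_smiles

    pool = distinct_canonical_smiles()
    if offset + n > len(pool):
        raise ConfigError(
            f"SMILES mode supports at most {len(pool)} compounds per target; "
            f"requested {offset + n}"
        )
    return pool[offset : offset + n]


def generate_temporal_pair(
    config: SyntheticConfig,
) -> tuple[SyntheticActivityData, SyntheticActivityData]:
    """Two-release structure: release B is release A plus new compounds.

    Per target, ``temporal_new_fraction * n_compounds`` new compounds (new
    structures, never seen in release A) are drawn with separability
    ``separability - temporal_shift``; ``temporal_shift=0`` makes old and
    new compounds exchangeable.
    """
    release_a = generate_activity_table(config)
    n_new = int(round(config.temporal_new_fraction * config.n_compounds))
    if n_new == 0:
        release_b = SyntheticActivityData(
            release_a.records.copy(), release_a.truth.copy(),
            dict(release_a.features), config,
        )
        return release_a, release_b

    new_cfg = replace(config, n_compounds=n_new)
    s_new = max(config.separability - config.temporal_shift, 0.0)
    new_seeds = derive_seeds(config.seed, config.n_targets, key="temporal")
    fam = (
        release_a.records.groupby("target_id")["family"].first().to_dict()
    )
    new_records, new_truth, features = [], [], dict(release_a.features)
    for t, target_id in enumerate(sorted(fam)):
        rec, truth, feats = _one_target(
            target_id, fam[target_id], new_cfg, int(new_seeds[t]),
            compound_prefix="N", separability=s_new,
            structure_offset=config.n_compounds,
        )
        new_records.append(rec)
        new_truth.append(truth)
        features.update(feats)
    release_b = SyntheticActivityData(
        pd.concat([release_a.records] + new_records, ignore_index=True),
        pd.concat([release_a.truth] + new_truth, ignore_index=True),
        features,
        config,
    )
    return release_a, release_b
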