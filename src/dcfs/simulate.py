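"""Synthetic cohorts with planted class-associated structure.

The generator emulates the statistical shape of a filtered somatic
variant matrix: a binary samples x features matrix in which a few
features are genuinely associated with one of the two classes, a few
are noisy copies of those (redundant), and the rest are class-
independent background.

Carrier model, per feature and sample:

* positive-associated: carrier probability pi0 + delta in the positive
  class, pi0 in the negative class;
* negative-associated: mirrored (pi0 + delta in the negative class);
* redundant: a copy of its source feature with independent
  Bernoulli(noise_flip) bit flips;
* null: Bernoulli(pi0) regardless of class.

delta (the carrier-probability gap) directly controls the population
point-biserial correlation between the feature and its class indicator,
which is exactly the quantity the dual merit consumes.

A second generator emits annotated variant *records* with controlled
fractions failing each filter step, so the 3-step filter can be tested
against an exact survivor count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .matrix import FeatureMatrix
from .variants import Consequence, Region, VariantRecord


@dataclass(frozen=True)
class SimSpec:
    """Cohort shape and effect sizes of one synthetic data set."""

    n_samples: int = 200
    n_features: int = 100
    pos_fraction: float = 0.5
    n_pos_assoc: int = 2
    n_neg_assoc: int = 2
    n_redundant: int = 0
    effect: float = 0.6          # carrier-probability gap delta
    background_rate: float = 0.1  # pi0
    noise_flip: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("need at least 2 samples and 1 feature")
        if not 0.0 < self.pos_fraction < 1.0:
            raise ValueError("pos_fraction must be in (0, 1)")
        if self.n_pos_assoc + self.n_neg_assoc + self.n_redundant > self.n_features:
            raise ValueError("planted features exceed n_features")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect (delta) must be in [0, 1]")
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate (pi0) must be in [0, 1)")
        if self.background_rate + self.effect > 1.0:
            raise ValueError(
                f"infeasible rates: pi0 + delta = {self.background_rate + self.effect} > 1"
            )
        if not 0.0 <= self.noise_flip <= 1.0:
            raise ValueError("noise_flip must be in [0, 1]")
        if self.n_redundant > 0 and self.n_pos_assoc + self.n_neg_assoc == 0:
            raise ValueError("redundant copies need at least one planted source feature")


@dataclass
class GroundTruth:
    """Partition of feature ids: planted, redundant (copy -> source), null."""

    pos_assoc: list[str]
    neg_assoc: list[str]
    redundant: dict[str, str] = field(default_factory=dict)
    null: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        # trailing newline keeps the artifact diff-friendly
        with open(path, "a") as fh:
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate(spec: SimSpec) -> tuple[FeatureMatrix, GroundTruth]:
    """Draw one cohort; fully determined by ``spec.seed``.

    Feature layout: positive-associated, then negative-associated, then
    redundant copies (cycling over the planted sources), then null.
    Sample class labels are a seeded permutation of round(S * pos_fraction)
    positives.
    """
    rng = np.random.default_rng(spec.seed)
    s, v = spec.n_samples, spec.n_features
    n_pos = int(round(s * spec.pos_fraction))
    if n_pos == 0 or n_pos == s:
        raise ValueError("both classes must be non-empty")
    c_pos = np.zeros(s, dtype=int)
    c_pos[:n_pos] = 1
    c_pos = rng.permutation(c_pos)

    pi0, delta = spec.background_rate, spec.effect
    X = np.zeros((s, v))
    sources: list[int] = []
    col = 0
    for _ in range(spec.n_pos_assoc):
        p = np.where(c_pos == 1, pi0 + delta, pi0)
        X[:, col] = rng.random(s) < p
        sources.append(col)
        col += 1
    for _ in range(spec.n_neg_assoc):
        p = np.where(c_pos == 0, pi0 + delta, pi0)
        X[:, col] = rng.random(s) < p
        sources.append(col)
        col += 1
    redundant: dict[int, int] = {}
    for j in range(spec.n_redundant):
        src = sources[j % len(sources)]
        flips = rng.random(s) < spec.noise_flip
        X[:, col] = np.where(flips, 1 - X[:, src], X[:, src])
        redundant[col] = src
        col += 1
    n_null = v - col
    if n_null:
        X[:, col:] = rng.random((s, n_null)) < pi0

    width = len(str(v - 1)) if v > 1 else 1
    feature_ids = [f"f{j:0{width}d}" for j in range(v)]
    sample_ids = [f"s{i:0{len(str(s - 1))}d}" for i in range(s)]
    truth = GroundTruth(
        pos_assoc=feature_ids[: spec.n_pos_assoc],
        neg_assoc=feature_ids[spec.n_pos_assoc : spec.n_pos_assoc + spec.n_neg_assoc],
        redundant={feature_ids[k]: feature_ids[src] for k, src in redundant.items()},
        null=feature_ids[col:],
    )
    fm = FeatureMatrix(X=X, sample_ids=sample_ids, feature_ids=feature_ids, c_pos=c_pos)
    return fm, truth


@dataclass(frozen=True)
class FilterMix:
    """Fractions of records constructed to fail each filter step; the
    remainder survive all three steps."""

    fail_step1: float = 0.0
    fail_step2: float = 0.0
    fail_step3: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.fail_step1, self.fail_step2, self.fail_step3)
        if min(fracs) < 0 or sum(fracs) > 1.0:
            raise ValueError("failure fractions must be nonnegative and sum to <= 1")


def generate_variant_records(
    n_records: int,
    mix: FilterMix = FilterMix(),
    n_samples: int = 10,
    seed: int = 0,
) -> list[VariantRecord]:
    """Emit annotated records with exact per-step failure counts.

    Exactly ``round(n_records * mix.fail_stepK)`` records fail step K
    (and pass the other steps' predicates), the rest survive all three,
    so the survivor count of the composite filter is computable in
    closed form. Records are spread round-robin across samples, at
    distinct genomic positions.
    """
    rng = np.random.default_rng(seed)
    n1 = int(round(n_records * mix.fail_step1))
    n2 = int(round(n_records * mix.fail_step2))
    n3 = int(round(n_records * mix.fail_step3))
    if n1 + n2 + n3 > n_records:
        raise ValueError("failure counts exceed n_records")
    bases = ("A", "C", "G", "T")
    records: list[VariantRecord] = []

    def base_kwargs(i: int) -> dict:
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        return dict(
            sample_id=f"s{i % n_samples}",
            chrom=str(1 + i % 22),
            pos=1000 + i,
            ref=ref,
            alt=alt,
            gene=f"GENE{i % 50}",
            region=Region.EXONIC,
            consequence=Consequence.NONSYNONYMOUS,
            in_gnomad=False,
            in_esp6500=False,
            in_exac=False,
            in_cosmic=bool(rng.random() < 0.1),
            tumor_freq=float(10 + rng.random() * 90),
            normal_freq=0.0,
            fisher_p=float(rng.random() * 0.01),
        )

    i = 0
    for _ in range(n1):  # fail step 1 only
        kw = base_kwargs(i)
        if rng.random() < 0.5:
            kw["region"] = (Region.INTRONIC, Region.INTERGENIC)[rng.integers(2)]
        else:
            kw["consequence"] = (Consequence.SYNONYMOUS, Consequence.AMBIGUOUS)[rng.integers(2)]
        records.append(VariantRecord(**kw))
        i += 1
    for _ in range(n2):  # fail step 2 only: in a population database, no rescue
        kw = base_kwargs(i)
        kw["in_cosmic"] = False
        flag = rng.integers(3)
        kw["in_gnomad"] = flag == 0
        kw["in_esp6500"] = flag == 1
        kw["in_exac"] = flag == 2
        records.append(VariantRecord(**kw))
        i += 1
    for _ in range(n3):  # fail step 3 only
        kw = base_kwargs(i)
        mode = rng.integers(3)
        if mode == 0:
            kw["tumor_freq"] = float(rng.random() * 9.99)
        elif mode == 1:
            kw["normal_freq"] = float(1 + rng.random() * 20)
        else:
            kw["fisher_p"] = float(0.011 + rng.random() * 0.5)
        records.append(VariantRecord(**kw))
        i += 1
    for _ in range(n_records - n1 - n2 - n3):  # survivors
        records.append(VariantRecord(**base_kwargs(i)))
        i += 1
    return records


__all__ = ["SimSpec", "GroundTruth", "generate", "FilterMix", "generate_variant_records"]
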