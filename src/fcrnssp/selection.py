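"""Three-stage construction of a compact training set.

Stage 1 estimates how many training chains, P, a dataset needs: chains
are added in seeded random increments and a fresh network is trained
at each size and scored on all remaining chains, producing an
accuracy-vs-size curve whose peak gives P.  Stage 2 builds candidate
training sets of roughly that size under different heuristics —
uniformly sampled chains, class-balanced residues, and chains spread
over the (fH, fE, fC) composition simplex by greedy farthest-point
sampling.  Stage 3 trains one classifier per candidate and ranks the
candidates by accuracy on a disjoint blind dataset; the winner is the
compact model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import SS3_STATES, ChainSet, ss_composition
from .features import FeatureSet
from .network import K_MAX, FCRNClassifier
from .scoring import MetricsReport, score_chains

__all__ = [
    "TrainingCurve",
    "CandidateSet",
    "stage1_training_curve",
    "build_candidate_sampled",
    "build_candidate_balanced",
    "build_candidate_spread",
    "stage3_blind_rank",
    "RankedCandidate",
]


@dataclass(frozen=True)
class TrainingCurve:
    """Accuracy as a function of training-set size (in chains)."""

    sizes: tuple[int, ...]
    q3_values: tuple[float, ...]
    chain_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.q3_values):
            raise ValueError("sizes and q3_values length mismatch")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")

    @property
    def estimated_P(self) -> int:
        """Size at the curve's maximum Q3 (first occurrence on ties)."""
        return self.sizes[int(np.argmax(self.q3_values))]

    def chains_at(self, size: int) -> tuple[str, ...]:
        """The training chains in play at a given curve size."""
        if size not in self.sizes:
            raise ValueError(f"size {size} is not a curve point")
        return self.chain_order[:size]


@dataclass(frozen=True)
class CandidateSet:
    """A candidate training set: whole chains, or residues for the
    class-balanced variant (members are (chain_id, residue_index))."""

    name: str
    kind: str  # 'sampled' | 'balanced' | 'spread' | 'curve_derived'
    chain_ids: tuple[str, ...] = ()
    residues: tuple[tuple[str, int], ...] = ()
    seed: int | None = None

    def training_features(self, features: FeatureSet) -> FeatureSet:
        """Select this candidate's feature rows from a FeatureSet."""
        if self.kind == "balanced":
            wanted = set(self.residues)
            mask = np.fromiter(
                (
                    (c, int(r)) in wanted
                    for c, r in zip(features.chain_ids, features.residue_indices)
                ),
                bool,
                len(features),
            )
            return features.select(mask)
        return features.for_chains(self.chain_ids)


def _fit_fcrn(
    train: FeatureSet, k_max: int, seed: int, **fcrn_kwargs
) -> FCRNClassifier:
    k = min(k_max, K_MAX, len(train))
    clf = FCRNClassifier(n_hidden=k, random_state=seed, **fcrn_kwargs)
    clf.fit(train.values, train.labels)
    return clf


def _predicted_pairs(
    clf: FCRNClassifier, chains: ChainSet, features: FeatureSet
) -> dict[str, tuple[str, str]]:
    """Per-chain (observed, predicted) strings over the feature rows."""
    pred = clf.predict(features.values)
    pairs: dict[str, tuple[str, str]] = {}
    for cid in chains.ids:
        mask = features.chain_ids == cid
        if not mask.any():
            continue
        order = np.argsort(features.residue_indices[mask])
        obs = "".join(features.labels[mask][order])
        prd = "".join(pred[mask][order])
        pairs[cid] = (obs, prd)
    return pairs


def stage1_training_curve(
    dataset: ChainSet,
    features: FeatureSet,
    step: int = 5,
    k_max: int = 100,
    seed: int = 0,
    **fcrn_kwargs,
) -> TrainingCurve:
    """Stage 1: seeded incremental training-curve estimation of P.

    Chains are shuffled once (seeded, uniform, without replacement) and
    consumed ``step`` at a time; at each size a network (hidden width
    min(k_max, samples)) is trained on the accumulated chains and Q3 is
    measured on all remaining chains.  The final size always leaves a
    non-empty test remainder.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(dataset)
    if n < 2 * step:
        raise ValueError(
            f"dataset of {n} chains is too small for step {step} "
            f"(need at least {2 * step})"
        )
    rng = np.random.default_rng(seed)
    order = [dataset.ids[i] for i in rng.permutation(n)]
    sizes = list(range(step, n, step))
    if sizes and sizes[-1] == n:  # defensive; range(stop=n) already excludes n
        sizes.pop()

    q3_values = []
    for size in sizes:
        train_ids = order[:size]
        test_ids = order[size:]
        train_fs = features.for_chains(train_ids)
        clf = _fit_fcrn(train_fs, k_max, seed, **fcrn_kwargs)
        test_fs = features.for_chains(test_ids)
        q3_values.append(100.0 * clf.score(test_fs.values, test_fs.labels))
    return TrainingCurve(tuple(sizes), tuple(q3_values), tuple(order))


def build_candidate_sampled(
    dataset: ChainSet,
    P: int,
    seed: int = 0,
    exclude: tuple[str, ...] = (),
    name: str = "sampled",
) -> CandidateSet:
    """P chains drawn uniformly without replacement, avoiding ``exclude``."""
    pool = [cid for cid in dataset.ids if cid not in set(exclude)]
    if len(pool) < P:
        raise ValueError(
            f"only {len(pool)} chains available after exclusions, need {P}"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=P, replace=False)]
    return CandidateSet(name, "sampled", chain_ids=tuple(chosen), seed=seed)


def build_candidate_balanced(
    dataset: ChainSet,
    features: FeatureSet,
    n_per_class: int,
    seed: int = 0,
    name: str = "balanced",
) -> CandidateSet:
    """Residue-level set with exactly n_per_class residues of each state."""
    rng = np.random.default_rng(seed)
    members: list[tuple[str, int]] = []
    for state in SS3_STATES:
        idx = np.nonzero(features.labels == state)[0]
        if len(idx) < n_per_class:
            raise ValueError(
                f"class {state} has only {len(idx)} residues, need {n_per_class}"
            )
        pick = rng.choice(idx, size=n_per_class, replace=False)
        members.extend(
            (features.chain_ids[i], int(features.residue_indices[i])) for i in pick
        )
    return CandidateSet(name, "balanced", residues=tuple(members), seed=seed)


def build_candidate_spread(
    dataset: ChainSet,
    P: int,
    seed: int | None = None,
    name: str = "spread",
) -> CandidateSet:
    """Chains spread over the composition simplex by farthest-point sampling.

    Starts from the chain nearest the dataset's mean (fH, fE, fC)
    composition, then repeatedly adds the chain whose minimum Euclidean
    distance to the already-chosen compositions is largest; ties break
    by dataset order.  Deterministic — ``seed`` is accepted for
    interface symmetry with the other builders but unused.
    """
    if len(dataset) < P:
        raise ValueError(f"dataset has {len(dataset)} chains, need {P}")
    comps = np.array([ss_composition(c.with_ss3()) for c in dataset])
    centroid = comps.mean(axis=0)
    start = int(np.argmin(np.linalg.norm(comps - centroid, axis=1)))
    chosen = [start]
    mindist = np.linalg.norm(comps - comps[start], axis=1)
    while len(chosen) < P:
        mindist[chosen] = -1.0  # never re-pick
        nxt = int(np.argmax(mindist))  # argmax takes the first on ties
        chosen.append(nxt)
        mindist = np.minimum(mindist, np.linalg.norm(comps - comps[nxt], axis=1))
    ids = tuple(dataset.ids[i] for i in chosen)
    return CandidateSet(name, "spread", chain_ids=ids, seed=seed)


@dataclass(frozen=True)
class RankedCandidate:
    candidate: CandidateSet
    blind_q3: float
    report: MetricsReport


def stage3_blind_rank(
    candidates: list[CandidateSet],
    train_features: FeatureSet,
    blind_chains: ChainSet,
    blind_features: FeatureSet,
    k_max: int = 100,
    seed: int = 0,
    **fcrn_kwargs,
) -> tuple[list[RankedCandidate], FCRNClassifier]:
    """Stage 3: rank candidates by blind-set Q3; the winner is the
    compact model.

    Every candidate must be disjoint from the blind dataset's chains.
    Returns the candidates sorted by descending blind Q3 (ties keep
    input order) together with the winning fitted classifier.
    """
    if not candidates:
        raise ValueError("no candidate sets supplied")
    blind_ids = set(blind_chains.ids)
    for cand in candidates:
        member_chains = set(cand.chain_ids) | {c for c, _ in cand.residues}
        overlap = member_chains & blind_ids
        if overlap:
            raise ValueError(
                f"candidate {cand.name!r} overlaps the blind set: "
                f"{sorted(overlap)}"
            )

    results: list[RankedCandidate] = []
    models: dict[str, FCRNClassifier] = {}
    for cand in candidates:
        train_fs = cand.training_features(train_features)
        if len(train_fs) == 0:
            raise ValueError(f"candidate {cand.name!r} selects no feature rows")
        clf = _fit_fcrn(train_fs, k_max, seed, **fcrn_kwargs)
        pairs = _predicted_pairs(clf, blind_chains, blind_features)
        report = score_chains(pairs)
        results.append(RankedCandidate(cand, report.q3, report))
        models[cand.name] = clf

    ranked = sorted(results, key=lambda r: -r.blind_q3)
    return ranked, models[ranked[0].candidate.name]
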