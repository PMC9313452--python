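"""Pipeline orchestration: contrastive pretraining, per-slice-ID classifier
training, student-level majority voting, subject-level k-fold
cross-validation and the rho sensitivity sweep.

Protocol (per cross-validation fold):

1. train one encoder+projection pair on *all* training-fold slices,
   regardless of slice ID, by minimizing the combined contrastive objective
   over augmented view pairs (default 2000 optimizer steps at paper scale);
2. embed the training slices and train 20 slice classifiers — classifier i
   sees only slice-ID-i instances, whose labels are inherited from their
   students (default 1000 steps);
3. for each held-out student, collect the 20 hard slice labels and vote:
   the student is labeled 1 iff strictly more than half the slices (>10 of
   20) vote 1; the vote fraction is the student's ROC score.

Folds partition *subjects*, so no slice of a test subject ever enters any
training step of its fold; every run carries a leakage audit recording the
per-fold train/test subject sets.  All randomness descends from a single
pipeline seed through numpy SeedSequence spawning, making runs
bit-reproducible; in particular, a run at rho=0 is bit-identical to a plain
SimCLR run at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .augmentation import AugmentConfig, make_pair
from .io_preprocess import SliceInstance, cohort_to_slices
from .losses import LossConfig, classifier_loss, combined_loss_grad
from .representation_model import (
    EncoderSpec,
    HeadSpec,
    RepresentationModel,
    build_classifier_head,
    build_model,
    classify_slice,
    slice_label,
)

__all__ = [
    "FoldAssignment",
    "PipelineConfig",
    "tiny_config",
    "VotingResult",
    "PAPER_RHO_SWEEP",
    "assign_folds",
    "train_contrastive",
    "embed_slices",
    "train_slice_classifiers",
    "aggregate_votes",
    "predict_student",
    "run_cross_validation",
    "rho_sweep",
]

# rho grid of the sensitivity analysis
PAPER_RHO_SWEEP = (0.0, 0.01, 0.02, 0.1, 0.3, 0.5)


@dataclass(frozen=True)
class FoldAssignment:
    """Balanced random partition of subjects into folds 1..k."""

    mapping: dict          # subject_id -> fold index (1-based)
    k: int
    seed: int

    def fold_of(self, subject_id) -> int:
        return self.mapping[subject_id]

    def subjects_in(self, fold: int) -> list:
        return [s for s, f in self.mapping.items() if f == fold]


def assign_folds(subject_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniformly random balanced partition; fold sizes differ by at most 1."""
    subject_ids = list(subject_ids)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > len(subject_ids):
        raise ValueError("more folds than subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    mapping = {subject_ids[idx]: (pos % k) + 1 for pos, idx in enumerate(order)}
    return FoldAssignment(mapping=mapping, k=k, seed=seed)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one cross-validated run needs.

    Defaults follow the study protocol (paper-scale encoder, 2000 contrastive
    iterations, 1000 classifier iterations, five folds, rho = 0.01); use
    ``tiny_config()`` for desk-scale runs.
    """

    encoder: EncoderSpec = EncoderSpec(variant="paper")
    augment: AugmentConfig = AugmentConfig()
    loss: LossConfig = LossConfig()
    n_iter_contrastive: int = 2000
    n_iter_classifier: int = 1000
    batch_size: int = 128        # positive pairs per contrastive step
    lr_contrastive: float = 1e-3
    lr_classifier: float = 1e-3
    k_folds: int = 5
    slice_axis: int = 0
    n_slices: int = 20
    seed: int = 0

    def with_rho(self, rho: float) -> "PipelineConfig":
        return replace(self, loss=replace(self.loss, rho=rho))


def tiny_config(seed: int = 0, rho: float = 0.01, n_iter_contrastive: int = 200,
                n_iter_classifier: int = 800, batch_size: int = 32) -> PipelineConfig:
    """Desk-scale configuration: tiny encoder, short contrastive stage, and a
    well-converged classifier stage (full-batch training is cheap at this
    size, so the classifier learning rate is raised to 3e-3)."""
    return PipelineConfig(
        encoder=EncoderSpec(variant="tiny"),
        loss=LossConfig(rho=rho, batch_size=batch_size),
        n_iter_contrastive=n_iter_contrastive,
        n_iter_classifier=n_iter_classifier,
        batch_size=batch_size,
        lr_classifier=3e-3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# contrastive stage


def train_contrastive(train_slices: list[SliceInstance], encoder_spec: EncoderSpec,
                      augment_config: AugmentConfig, loss_config: LossConfig,
                      n_iter: int, seed: int, batch_size: int = 128,
                      lr: float = 1e-3) -> tuple[RepresentationModel, list[float]]:
    """Minimize the combined contrastive objective for `n_iter` Adam steps.

    One iteration = one optimizer step on one minibatch of `batch_size`
    positive pairs (each pair is two augmented views of one slice).  Returns
    the trained model and the per-iteration loss trajectory.  With
    ``n_iter=0`` the returned parameters equal the seeded initialization.
    """
    if not train_slices:
        raise ValueError("empty training slice set")
    root = np.random.SeedSequence(seed)
    init_seed, sample_ss, augment_ss = root.spawn(3)
    model = build_model(encoder_spec, seed=init_seed.generate_state(1)[0] % (2**31))
    sampler = np.random.default_rng(sample_ss)
    aug_rng = np.random.default_rng(augment_ss)
    optimizer = nn.Adam(model.parameters(), lr=lr)

    n = len(train_slices)
    trajectory: list[float] = []
    for _ in range(n_iter):
        take = min(batch_size, n)
        idx = sampler.choice(n, size=take, replace=False)
        views = []
        for i in idx:
            a, b = make_pair(train_slices[i].pixels, augment_config, aug_rng)
            views.append(a)
            views.append(b)
        x = np.stack(views)[:, None, :, :]
        h = model.encoder.forward(x, train=True)
        z = model.projection.forward(h, train=True)
        loss, dz = combined_loss_grad(z, loss_config)
        dh = model.projection.backward(dz)
        model.encoder.backward(dh)
        optimizer.step()
        trajectory.append(loss)
    return model, trajectory


@dataclass
class SliceEmbeddings:
    """Per-slice encoder features (for visualization) and projections z
    (the classifier input), aligned with subject/slice metadata."""

    subject_ids: np.ndarray
    slice_ids: np.ndarray
    labels: np.ndarray
    features: np.ndarray     # (n, encoder feature_dim)
    projections: np.ndarray  # (n, projection width)


def embed_slices(slices: list[SliceInstance], model: RepresentationModel,
                 batch_size: int = 256) -> SliceEmbeddings:
    """Deterministic evaluation-mode embedding of every slice."""
    feats, projs = [], []
    for start in range(0, len(slices), batch_size):
        chunk = slices[start : start + batch_size]
        x = np.stack([s.pixels for s in chunk])
        h = model.encode(x, train=False)
        feats.append(h)
        projs.append(model.project(h, train=False))
    if not slices:
        raise ValueError("no slices to embed")
    return SliceEmbeddings(
        subject_ids=np.array([s.subject_id for s in slices]),
        slice_ids=np.array([s.slice_id for s in slices]),
        labels=np.array([s.label for s in slices]),
        features=np.vstack(feats),
        projections=np.vstack(projs),
    )


# ---------------------------------------------------------------------------
# classifier stage


@dataclass
class SliceClassifierBank:
    """The 20 per-slice-ID classifiers plus a training audit.

    ``audit[i]`` is the set of slice IDs of the rows classifier i was trained
    on — the isolation contract requires it to be exactly ``{i}``.
    """

    classifiers: dict
    audit: dict
    loss_trajectories: dict


def train_slice_classifiers(projections: np.ndarray, labels: np.ndarray,
                            slice_ids: np.ndarray, n_iter: int, seed: int,
                            lr: float = 1e-3, n_slices: int = 20,
                            head_spec: HeadSpec | None = None) -> SliceClassifierBank:
    """Train one sigmoid MLP per slice ID on that ID's instances only,
    minimizing mean squared error to the inherited student labels."""
    projections = np.asarray(projections, dtype=float)
    labels = np.asarray(labels, dtype=float)
    slice_ids = np.asarray(slice_ids)
    present = set(int(s) for s in slice_ids)
    missing = [i for i in range(1, n_slices + 1) if i not in present]
    if missing:
        raise ValueError(f"missing slice IDs in training data: {missing}")
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(n_slices)
    classifiers, audit, trajectories = {}, {}, {}
    d = projections.shape[1]
    clf_widths = head_spec.classifier_widths if head_spec is not None else (d, max(2, d // 2), 1)
    if clf_widths[0] != d:
        raise ValueError(f"classifier input width {clf_widths[0]} != projection width {d}")
    for i in range(1, n_slices + 1):
        mask = slice_ids == i
        x, y = projections[mask], labels[mask]
        audit[i] = set(int(s) for s in slice_ids[mask])
        rng = np.random.default_rng(seeds[i - 1].generate_state(1)[0] % (2**31))
        clf = build_classifier_head(HeadSpec(projection_widths=(d, d, d),
                                             classifier_widths=clf_widths), rng)
        optimizer = nn.Adam(clf.parameters(), lr=lr)
        traj = []
        for _ in range(n_iter):
            p = clf.forward(x, train=True).ravel()
            traj.append(classifier_loss(p, y))
            dp = (2.0 / len(y)) * (p - y)
            clf.backward(dp[:, None])
            optimizer.step()
        classifiers[i] = clf
        trajectories[i] = traj
    return SliceClassifierBank(classifiers=classifiers, audit=audit, loss_trajectories=trajectories)


# ---------------------------------------------------------------------------
# voting


@dataclass(frozen=True)
class VotingResult:
    """Per-student ensemble outcome: the 20 slice labels, their sum, the
    voted label (1 iff the sum strictly exceeds half the slice count) and
    the vote-fraction score used for ROC analysis."""

    subject_id: str
    slice_labels: tuple
    vote_sum: int
    final_label: int
    score: float


def aggregate_votes(slice_labels, subject_id: str = "") -> VotingResult:
    """Apply the voting rule to a vector of hard slice labels."""
    labels = np.asarray(slice_labels).astype(int)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("slice_labels must be a non-empty vector")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("slice labels must be binary")
    vote_sum = int(labels.sum())
    n = labels.size
    final = 1 if vote_sum > n // 2 else 0   # for 20 slices: 1 iff sum > 10
    return VotingResult(subject_id=subject_id, slice_labels=tuple(int(v) for v in labels),
                        vote_sum=vote_sum, final_label=final, score=vote_sum / n)


def predict_student(bank: SliceClassifierBank, student_projections: dict,
                    subject_id: str = "", n_slices: int = 20) -> VotingResult:
    """Vote a student's label from their per-slice projections.

    `student_projections` maps slice ID -> projection vector; exactly one
    entry per slice ID 1..n_slices is required.
    """
    if set(student_projections) != set(range(1, n_slices + 1)):
        raise ValueError(f"need exactly one projection per slice ID 1..{n_slices}")
    labels = []
    for i in range(1, n_slices + 1):
        prob = classify_slice(bank.classifiers[i], student_projections[i])[0]
        labels.append(int(slice_label(prob)))
    return aggregate_votes(labels, subject_id=subject_id)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Cross-validated predictions at both levels plus the leakage audit."""

    student_table: pd.DataFrame   # subject_id, fold, label, vote_sum, score, pred
    slice_table: pd.DataFrame     # subject_id, fold, slice_id, label, prob, pred
    fold_assignment: FoldAssignment
    audit: list                   # per fold: {"fold", "train_subjects", "test_subjects"}
    loss_trajectories: dict       # fold -> contrastive loss trajectory

    def leakage_free(self) -> bool:
        """True iff no subject appears in both sides of any fold and every
        subject is tested exactly once."""
        tested = []
        for entry in self.audit:
            if entry["train_subjects"] & entry["test_subjects"]:
                return False
            tested.extend(entry["test_subjects"])
        return len(tested) == len(set(tested)) == len(self.fold_assignment.mapping)


def run_cross_validation(cohort, config: PipelineConfig) -> CVResult:
    """Subject-level k-fold cross-validation of the full workflow."""
    if not cohort:
        raise ValueError("empty cohort")
    slices = cohort_to_slices(cohort, axis=config.slice_axis, normalize=True)
    subject_ids = [rec.subject_id for rec in cohort]
    root = np.random.SeedSequence(config.seed)
    fold_ss, *fold_seeds = root.spawn(1 + 2 * config.k_folds)
    folds = assign_folds(subject_ids, k=config.k_folds,
                         seed=int(fold_ss.generate_state(1)[0] % (2**31)))

    label_of = {rec.subject_id: rec.label for rec in cohort}
    student_rows, slice_rows, audit = [], [], []
    trajectories = {}
    for fold in range(1, config.k_folds + 1):
        test_subjects = set(folds.subjects_in(fold))
        train_subjects = set(subject_ids) - test_subjects
        audit.append({"fold": fold, "train_subjects": train_subjects,
                      "test_subjects": test_subjects})
        train_slices = [s for s in slices if s.subject_id in train_subjects]
        test_slices = [s for s in slices if s.subject_id in test_subjects]

        cl_seed = int(fold_seeds[2 * (fold - 1)].generate_state(1)[0] % (2**31))
        clf_seed = int(fold_seeds[2 * fold - 1].generate_state(1)[0] % (2**31))

        model, traj = train_contrastive(
            train_slices, config.encoder, config.augment, config.loss,
            n_iter=config.n_iter_contrastive, seed=cl_seed,
            batch_size=config.batch_size, lr=config.lr_contrastive,
        )
        trajectories[fold] = traj

        train_emb = embed_slices(train_slices, model)
        bank = train_slice_classifiers(
            train_emb.projections, train_emb.labels, train_emb.slice_ids,
            n_iter=config.n_iter_classifier, seed=clf_seed,
            lr=config.lr_classifier, n_slices=config.n_slices,
            head_spec=model.head_spec,
        )

        test_emb = embed_slices(test_slices, model)
        for sid in sorted(test_subjects):
            mask = test_emb.subject_ids == sid
            s_ids = test_emb.slice_ids[mask]
            projs = {int(i): test_emb.projections[mask][j] for j, i in enumerate(s_ids)}
            result = predict_student(bank, projs, subject_id=sid, n_slices=config.n_slices)
            student_rows.append({"subject_id": sid, "fold": fold, "label": label_of[sid],
                                 "vote_sum": result.vote_sum, "score": result.score,
                                 "pred": result.final_label})
            for j, i in enumerate(s_ids):
                prob = classify_slice(bank.classifiers[int(i)], test_emb.projections[mask][j])[0]
                slice_rows.append({"subject_id": sid, "fold": fold, "slice_id": int(i),
                                   "label": label_of[sid], "prob": float(prob),
                                   "pred": int(slice_label(prob))})

    student_table = pd.DataFrame(student_rows).sort_values("subject_id").reset_index(drop=True)
    slice_table = pd.DataFrame(slice_rows).sort_values(["subject_id", "slice_id"]).reset_index(drop=True)
    return CVResult(student_table=student_table, slice_table=slice_table,
                    fold_assignment=folds, audit=audit, loss_trajectories=trajectories)


def rho_sweep(cohort, rho_values, config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full cross-validation once per rho; the rho=0 arm is the plain
    SimCLR baseline (the combined objective degenerates to NT-Xent).

    Returns a (table, results) pair: the table has one row per rho with
    student- and image-level accuracy; results maps rho -> CVResult.
    """
    rho_values = list(rho_values)
    if any(r < 0 for r in rho_values):
        raise ValueError("rho must be non-negative")
    rows, results = [], {}
    for rho in rho_values:
        res = run_cross_validation(cohort, config.with_rho(rho))
        student_acc = float((res.student_table["pred"] == res.student_table["label"]).mean())
        image_acc = float((res.slice_table["pred"] == res.slice_table["label"]).mean())
        rows.append({"rho": rho, "student_acc": student_acc, "image_acc": image_acc})
        results[rho] = res
    return pd.DataFrame(rows), results
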