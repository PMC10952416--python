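"""Cross-session duplicate-cell identification and removal.

Cells recorded over days are found by (1) prescreening same-tetrode,
consecutive-session cell pairs by rate-map correlation (> 0.375, place fields
assumed stable across days), (2) comparing waveforms with the two Tolias
distances - d1, the normalised residual after optimally rescaling each
channel, captures shape differences; d2, the spread of the per-channel scale
factors, captures changes in the amplitude profile across the four tetrode
channels - (3) converting the distance pair into a posterior probability of
"same cell" with a per-animal linear discriminant trained on within-session
(same) and first-versus-last-session (different) pairs, and (4) resolving
convergence/divergence conflicts: a posterior gap above 0.1 decides by
posterior, otherwise the higher spatial correlation wins.  Duplicate chains
keep only their first-session member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .remapping import map_pearson

SPATIAL_PRESCREEN = 0.375
POSTERIOR_MIN = 0.5
POSTERIOR_GAP = 0.1


# ---------------------------------------------------------------------------
# Tolias distances
# ---------------------------------------------------------------------------


def channel_scale_factors(wf_a: np.ndarray, wf_b: np.ndarray) -> np.ndarray:
    """Least-squares scale ``alpha_c = argmin ||a_c - alpha b_c||`` per channel."""
    a = np.asarray(wf_a, dtype=float)
    b = np.asarray(wf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must share channel and sample counts")
    bb = np.sum(b * b, axis=1)
    if np.any(bb == 0):
        raise ValueError("zero-energy channel in second waveform")
    return np.sum(a * b, axis=1) / bb


def tolias_d1(wf_a: np.ndarray, wf_b: np.ndarray) -> float:
    """Shape distance: pooled Euclidean residual after per-channel optimal
    rescaling, normalised by the pooled norm of ``wf_a``.  0 for identical
    shapes regardless of uniform rescaling; 1 for channel-wise orthogonal
    waveforms."""
    a = np.asarray(wf_a, dtype=float)
    b = np.asarray(wf_b, dtype=float)
    alpha = channel_scale_factors(a, b)
    resid = np.linalg.norm(a - alpha[:, None] * b, axis=1)
    norm = np.linalg.norm(a, axis=1)
    total = norm.sum()
    if total == 0:
        raise ValueError("zero-energy reference waveform")
    return float(resid.sum() / total)


def tolias_d2(wf_a: np.ndarray, wf_b: np.ndarray) -> float:
    """Amplitude-profile distance: standard deviation (ddof 0) of the log
    per-channel scale factors.  0 iff the amplitude ratios are uniform across
    channels; non-positive scale factors (sign-flipped channels) are invalid."""
    alpha = channel_scale_factors(wf_a, wf_b)
    if np.any(alpha <= 0):
        raise ValueError("non-positive channel scale factor (sign flip)")
    return float(np.std(np.log(alpha)))


# ---------------------------------------------------------------------------
# discriminant matcher
# ---------------------------------------------------------------------------


@dataclass
class TrainedMatcher:
    model: LinearDiscriminantAnalysis
    training_accuracy: float
    class_means: dict
    n_same: int
    n_different: int

    def posterior_same(self, d1: float, d2: float) -> float:
        proba = self.model.predict_proba(np.array([[d1, d2]]))[0]
        i_same = list(self.model.classes_).index(1)
        return float(proba[i_same])


def train_matcher(
    same_pairs: Sequence, different_pairs: Sequence, min_pairs: int = 10
) -> TrainedMatcher:
    """Fit the per-animal linear discriminant on (d1, d2) feature pairs.

    ``same_pairs`` come from the same sorted unit across the two-box trials of
    one session; ``different_pairs`` from distinct units in the first and last
    sessions.  Equal class priors (no prior adjustment).
    """

    same = np.asarray(same_pairs, dtype=float).reshape(-1, 2)
    diff = np.asarray(different_pairs, dtype=float).reshape(-1, 2)
    if len(same) < min_pairs or len(diff) < min_pairs:
        raise ValueError(f"need >= {min_pairs} training pairs per class")
    X = np.vstack([same, diff])
    y = np.concatenate([np.ones(len(same), int), np.zeros(len(diff), int)])
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate training features (zero variance)")
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(X, y)
    acc = float(lda.score(X, y))
    return TrainedMatcher(
        model=lda,
        training_accuracy=acc,
        class_means={"same": same.mean(axis=0), "different": diff.mean(axis=0)},
        n_same=len(same),
        n_different=len(diff),
    )


def training_pairs_from_corpus(sessions: list) -> tuple:
    """(same, different) (d1, d2) training sets from a tracking corpus.

    Same-cell pairs compare each unit's waveforms across the two-box trials
    within a session; different-cell pairs compare distinct units between the
    very first and very last session.
    """

    same, different = [], []
    for units in sessions:
        for u in units:
            tw = u.trial_waveforms
            for i in range(len(tw)):
                for j in range(i + 1, len(tw)):
                    same.append((tolias_d1(tw[i], tw[j]), tolias_d2(tw[i], tw[j])))
    for ua in sessions[0]:
        for ub in sessions[-1]:
            if ua.true_id == ub.true_id:
                continue
            try:
                different.append(
                    (tolias_d1(ua.waveform, ub.waveform),
                     tolias_d2(ua.waveform, ub.waveform))
                )
            except ValueError:
                continue
    return same, different


# ---------------------------------------------------------------------------
# matching and resolution
# ---------------------------------------------------------------------------


@dataclass
class MatchDecision:
    cell_a: str  # earlier-session label
    cell_b: str  # later-session label
    boundary: tuple  # (session index a, session index b)
    d1: float
    d2: float
    spatial_r: float
    posterior_same: float
    decided_same: bool
    resolution: str  # direct | convergence-winner | divergence-winner | loser | ...


def resolve_conflicts(decisions: list, gap: float = POSTERIOR_GAP) -> None:
    """Enforce a partial matching per session boundary, in place.

    Wherever several decided pairs share a cell (convergence: many earlier ->
    one later; divergence: one earlier -> many later), the pair with the
    higher posterior wins if the posterior gap exceeds ``gap``; otherwise the
    pair with the higher spatial correlation wins.  Losers are undecided.
    """

    def winner(cands):
        cands = sorted(cands, key=lambda d: -d.posterior_same)
        if cands[0].posterior_same - cands[1].posterior_same > gap:
            return cands[0]
        near = [c for c in cands if cands[0].posterior_same - c.posterior_same <= gap]
        return max(near, key=lambda d: d.spatial_r)

    changed = True
    while changed:
        changed = False
        live = [d for d in decisions if d.decided_same]
        for side, kind in (("cell_b", "convergence"), ("cell_a", "divergence")):
            groups = {}
            for d in live:
                groups.setdefault((d.boundary, getattr(d, side)), []).append(d)
            for cands in groups.values():
                if len(cands) < 2:
                    continue
                win = winner(cands)
                for d in cands:
                    if d is win:
                        d.resolution = f"{kind}-winner"
                    else:
                        d.decided_same = False
                        d.resolution = "loser"
                changed = True
            if changed:
                break


def match_cells(
    sessions: list,
    matcher: TrainedMatcher,
    spatial_threshold: float = SPATIAL_PRESCREEN,
    posterior_min: float = POSTERIOR_MIN,
    posterior_gap: float = POSTERIOR_GAP,
) -> list:
    """Candidate same-cell decisions across all consecutive session boundaries.

    Candidates are same-tetrode pairs whose rate-map correlation exceeds the
    spatial prescreen; each gets Tolias distances (earlier -> later direction)
    and a classifier posterior, is decided when the posterior exceeds 0.5,
    and conflicts are then resolved to a partial matching.
    """

    decisions = []
    for s in range(len(sessions) - 1):
        for ua in sessions[s]:
            for ub in sessions[s + 1]:
                if ua.tetrode != ub.tetrode:
                    continue
                if ua.waveform is None or ub.waveform is None:
                    continue
                r, _ = map_pearson(ua.ratemap, ub.ratemap)
                if not (np.isfinite(r) and r > spatial_threshold):
                    continue
                try:
                    d1 = tolias_d1(ua.waveform, ub.waveform)
                    d2 = tolias_d2(ua.waveform, ub.waveform)
                except ValueError:
                    decisions.append(
                        MatchDecision(ua.label, ub.label, (s, s + 1),
                                      float("nan"), float("nan"), r, 0.0,
                                      False, "invalid-waveform-pair")
                    )
                    continue
                post = matcher.posterior_same(d1, d2)
                decided = post > posterior_min
                decisions.append(
                    MatchDecision(
                        ua.label, ub.label, (s, s + 1), d1, d2, r, post,
                        decided, "direct" if decided else "below-posterior",
                    )
                )
    resolve_conflicts(decisions, posterior_gap)
    return decisions


def dedupe(decisions: list, sessions: list) -> dict:
    """Collapse same-cell chains, keeping each chain's first-session member.

    Returns ``{"kept": [(session, label)], "removed": [...], "chains":
    {label of first member: [labels...]}, "multi_session_counts": {chain
    length: n}}``.
    """

    link = {}
    for d in decisions:
        if d.decided_same:
            link[(d.boundary[0], d.cell_a)] = (d.boundary[1], d.cell_b)
    successors = set(link.values())
    chains = {}
    for start in sorted(link):
        if start in successors:
            continue
        chain = [start]
        while chain[-1] in link:
            nxt = link[chain[-1]]
            assert nxt not in chain, "cyclic same-cell links"
            chain.append(nxt)
        chains[start] = chain
    removed = {node for chain in chains.values() for node in chain[1:]}
    kept, dropped = [], []
    for s, units in enumerate(sessions):
        for u in units:
            node = (s, u.label)
            (dropped if node in removed else kept).append(node)
    counts = {}
    for chain in chains.values():
        counts[len(chain)] = counts.get(len(chain), 0) + 1
    return {
        "kept": kept,
        "removed": dropped,
        "chains": {c[0][1]: [lbl for _, lbl in c] for c in chains.values()},
        "multi_session_counts": counts,
    }
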