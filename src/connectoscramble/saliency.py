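"""Guided Grad-CAM saliency in edge space, aggregated over an ensemble.

For a trained member and an input grid, Grad-CAM weights each convolutional
feature map by the spatial mean of the target-class logit gradient, combines
the maps with those weights, and rectifies the result; the coarse map is
broadcast over each grid row and multiplied elementwise by the
guided-backpropagation input gradient (negative gradients zeroed at every
ReLU). The product is rectified and mapped through the member's inverse edge
permutation back to (edge, band) space, so saliencies from members with
different scramblings are comparable edge by edge.

Per-subject maps average the saliency over members x {class 0, class 1} x 3
bands into one symmetric, non-negative 116x116 matrix. Network relevance is
quantified by Cohen's d of CAM values on a network's edge set against all
remaining edges — an effect size, deliberately not a significance test,
because the number of subject-edge values is enormous.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from . import edges, member as member_mod, nn


def member_cam(
    trained: member_mod.TrainedMember,
    grids: np.ndarray,
    target_class: int,
    batch_size: int = 128,
) -> np.ndarray:
    """Guided Grad-CAM saliency for a batch of grids: (n, 3, E_grid).

    ``grids`` is (n, rows, cols, 3) already scrambled with the member's own
    codec. Output is in edge order (through the inverse codec), per band.
    """
    net = trained.network
    if net.conv_relu_index is None:
        raise ValueError("Grad-CAM requires the convolutional architecture")
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    outs = []
    for i in range(0, len(grids), batch_size):
        batch = grids[i:i + batch_size].astype(nn.DTYPE)
        logits = net.forward(batch, training=False, record=True)
        fmaps = net.feature_maps                      # (B, R, F)
        grad_logits = np.zeros_like(logits)
        grad_logits[:, target_class] = 1.0
        guided = net.backward_from_logits(
            grad_logits, guided=True, record=True
        )                                             # (B, R, C, 3)
        fgrads = net.feature_map_grads                # (B, R, F)
        alpha = fgrads.mean(axis=1)                   # (B, F)
        cam_rows = np.maximum(
            np.einsum("brf,bf->br", fmaps, alpha), 0.0
        )                                             # (B, R)
        product = np.maximum(cam_rows[:, :, None, None] * guided, 0.0)
        outs.append(member_mod.unscramble(product, trained.codec))
    return np.concatenate(outs)


@dataclass
class SubjectCAM:
    """One subject's ensemble-averaged class activation map."""

    subject_id: str
    cam: np.ndarray          # 116 x 116, symmetric, non-negative, zero diagonal
    n_members: int

    def __post_init__(self):
        if not np.allclose(self.cam, self.cam.T):
            raise ValueError("subject CAM must be symmetric")
        if (self.cam < 0).any() or not np.isfinite(self.cam).all():
            raise ValueError("subject CAM must be non-negative and finite")


def aggregate_cams(
    members: list[member_mod.TrainedMember],
    connectomes: np.ndarray,
    subject_ids: np.ndarray,
) -> dict[str, SubjectCAM]:
    """Average edge saliency over members, both classes and all bands.

    Each member contributes CAMs for the subjects of its own held-out test
    set; members' ``test_ids`` index rows of ``connectomes`` (and of
    ``subject_ids``, which provides the output keys). Subjects appearing in
    no member's test set are excluded with a warning. Values hold one
    symmetric 116x116 map each (diagonal zero).
    """
    if not members:
        raise ValueError("need at least one trained member")
    subject_ids = np.asarray(subject_ids)
    n_edges_full = edges.N_EDGES
    sums = np.zeros((len(subject_ids), n_edges_full))
    counts = np.zeros(len(subject_ids), dtype=int)

    for tm in members:
        rows = np.asarray(tm.test_ids, dtype=np.int64)
        grids = member_mod.scramble(
            connectomes[rows], tm.codec, mask=tm.mask
        )
        per_class = []
        for cls in (0, 1):
            cam = member_cam(tm, grids, cls)          # (B, 3, E_grid)
            per_class.append(cam.mean(axis=1))        # band mean -> (B, E_grid)
        edge_vals = 0.5 * (per_class[0] + per_class[1])
        if tm.mask is not None:
            full = np.zeros((len(rows), n_edges_full))
            full[:, np.unique(tm.mask)] = edge_vals
            edge_vals = full
        sums[rows] += edge_vals
        counts[rows] += 1

    covered = counts > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} subject(s) appear in no member's test "
            "set and were excluded from CAM aggregation"
        )
    out = {}
    for i in np.flatnonzero(covered):
        mat = edges.unvectorize(sums[i] / counts[i], diagonal=0.0)
        out[str(subject_ids[i])] = SubjectCAM(
            subject_id=str(subject_ids[i]), cam=mat, n_members=int(counts[i])
        )
    return out


def cohens_d(group: np.ndarray, rest: np.ndarray) -> float:
    """Pooled-standard-deviation Cohen's d (positive = group larger)."""
    n1, n2 = len(group), len(rest)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs at least two values per group")
    s1, s2 = group.var(ddof=1), rest.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        return np.nan
    return float((group.mean() - rest.mean()) / pooled)


def network_effect_sizes(
    cams: dict[str, SubjectCAM],
    networks: dict,
    table: pd.DataFrame,
    modes: tuple[str, ...] = ("inner", "connecting"),
) -> pd.DataFrame:
    """Cohen's d of CAM edge values inside vs outside each network edge set.

    One row per network x edge mode x stratum (rest/task), pooling all
    subject-edge values within the stratum. Columns: network, edge_set,
    stratum, d, n_in, n_out. Zero pooled sd yields d = NaN.
    """
    lookup = dict(zip(table["subject_id"].astype(str), table["condition"]))
    vecs, conds = [], []
    for sid, scam in cams.items():
        vecs.append(edges.vectorize(scam.cam))
        conds.append(lookup[sid])
    vecs = np.asarray(vecs)
    conds = np.asarray(conds)

    rows = []
    for name, net in networks.items():
        for mode in modes:
            edge_set = net.edge_set(mode)
            other = np.setdiff1d(np.arange(edges.N_EDGES), edge_set)
            for stratum, code in (("rest", 0), ("task", 1)):
                sel = conds == code
                group = vecs[np.ix_(sel, edge_set)].ravel()
                rest_vals = vecs[np.ix_(sel, other)].ravel()
                d = (
                    cohens_d(group, rest_vals)
                    if len(group) > 1 and len(rest_vals) > 1 else np.nan
                )
                rows.append({
                    "network": name, "edge_set": mode, "stratum": stratum,
                    "d": d, "n_in": len(group), "n_out": len(rest_vals),
                })
    return pd.DataFrame(rows)
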