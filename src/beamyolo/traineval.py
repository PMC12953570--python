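"""Desk-scale training and COCO-style evaluation.

The detector's heads emit, per pyramid level, 4 * reg_max
distribution-focal box logits and ``nc`` class logits per cell.
Decoding takes the softmax expectation over the reg_max distance bins
(in cell units), turns cell-relative LTRB distances into normalized
boxes, and applies class-wise non-maximum suppression.

Training uses centre-based assignment: each ground-truth box picks the
pyramid level whose stride makes it roughly four cells wide and marks
cells within a small radius of its centre as positives.  The loss is
focal binary cross-entropy on class scores, generalized-IoU on decoded
boxes, and distribution-focal regression on the distance bins.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import autograd
import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten
from autograd.tracer import getval

from .assembly import DetectionModel
from .nn import functional as F
from .synthdata import BoxAnnotation


@dataclass(frozen=True)
class Detection:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float

    def __post_init__(self):
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")

    def corners(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    map50: float
    map50_95: float

    def as_dict(self) -> Dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "map50": self.map50, "map50_95": self.map50_95}


@dataclass
class TrainConfig:
    epochs: int = 250
    batch_size: int = 16
    lr: float = 0.01
    momentum: float = 0.937
    image_size: int = 640
    warmup_steps: int = 20
    box_weight: float = 7.5
    cls_weight: float = 1.0
    dfl_weight: float = 1.5
    focal_gamma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or not (0 <= self.lr < 1):
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# geometry


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (N, 4) / (M, 4) corner-format box arrays."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> List[int]:
    """Greedy non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores)
    keep: List[int] = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    ious = iou_matrix(boxes, boxes) if len(boxes) else np.zeros((0, 0))
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        suppressed |= ious[i] > iou_thresh
        suppressed[i] = True
    return keep


# ---------------------------------------------------------------------------
# decoding


def _grid_centres(h: int, w: int) -> Tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0:h, 0:w]
    return ys + 0.5, xs + 0.5


def decode_predictions(head_outputs, strides=(8, 16, 32), reg_max: int = 16,
                       conf_thresh: float = 0.25, iou_thresh: float = 0.45,
                       max_det: int = 300) -> List[List[Detection]]:
    """Decode raw head maps into per-image detection lists."""
    if not (0 <= conf_thresh <= 1 and 0 <= iou_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    batch = getval(head_outputs[0][0]).shape[0]
    results: List[List[Detection]] = []
    for b in range(batch):
        boxes, scores, classes = [], [], []
        for (box_map, cls_map), stride in zip(head_outputs, strides):
            bm = getval(box_map)[b]
            cm = getval(cls_map)[b]
            _, H, W = bm.shape
            img_h, img_w = H * stride, W * stride
            dist = bm.reshape(4, reg_max, H, W)
            dist = np.exp(dist - dist.max(axis=1, keepdims=True))
            dist = dist / dist.sum(axis=1, keepdims=True)
            d = np.tensordot(np.arange(reg_max), dist, axes=([0], [1]))  # (4,H,W) cells
            cy, cx = _grid_centres(H, W)
            x0 = (cx - d[0]) * stride / img_w
            y0 = (cy - d[1]) * stride / img_h
            x1 = (cx + d[2]) * stride / img_w
            y1 = (cy + d[3]) * stride / img_h
            prob = 1.0 / (1.0 + np.exp(-cm))  # (nc,H,W)
            cls_id = prob.argmax(axis=0)
            conf = prob.max(axis=0)
            m = conf >= conf_thresh
            if not m.any():
                continue
            boxes.append(np.stack([x0[m], y0[m], x1[m], y1[m]], axis=1))
            scores.append(conf[m])
            classes.append(cls_id[m])
        dets: List[Detection] = []
        if boxes:
            boxes = np.clip(np.concatenate(boxes), 0.0, 1.0)
            scores = np.concatenate(scores)
            classes = np.concatenate(classes)
            for c in np.unique(classes):
                idx = np.nonzero(classes == c)[0]
                for k in nms(boxes[idx], scores[idx], iou_thresh):
                    i = idx[k]
                    x0, y0, x1, y1 = boxes[i]
                    if x1 <= x0 or y1 <= y0:
                        continue
                    dets.append(Detection(int(c), (x0 + x1) / 2, (y0 + y1) / 2,
                                          x1 - x0, y1 - y0, float(scores[i])))
            dets.sort(key=lambda d: -d.confidence)
            dets = dets[:max_det]
        results.append(dets)
    return results


# ---------------------------------------------------------------------------
# evaluation


IOU_THRESHOLDS = np.round(np.arange(0.50, 0.96, 0.05), 2)
RECALL_GRID = np.linspace(0, 1, 101)


def _ap_single(tp_flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from confidence-ordered TP flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp_flags) == 0:
        return 0.0
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~tp_flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    # precision envelope (monotone nonincreasing from the right)
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in RECALL_GRID:
        idx = np.searchsorted(recall, r, side="left")
        ap += prec_env[idx] if idx < len(prec_env) else 0.0
    return ap / len(RECALL_GRID)


def _match_class(dets, gts, thresh: float) -> np.ndarray:
    """Greedy confidence-descending matching; returns TP flags in
    confidence order."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    matched = [np.zeros(len(g), dtype=bool) for g in gts]
    flags = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        img, _conf, box = dets[i]
        if len(gts[img]) == 0:
            continue
        ious = iou_matrix(box[None], gts[img])[0]
        ious[matched[img]] = -1.0
        j = int(ious.argmax())
        if ious[j] >= thresh:
            flags[rank] = True
            matched[img][j] = True
    return flags


def evaluate(detections: Sequence[Sequence[Detection]],
             ground_truth: Sequence[Sequence[BoxAnnotation]],
             conf_thresh: float = 0.25) -> EvalResult:
    """Precision/recall at ``conf_thresh`` (IoU 0.5) plus mAP@50 and
    mAP@50-95 with 101-point interpolation, averaged over classes
    present in the ground truth."""
    if len(detections) != len(ground_truth):
        raise ValueError("detections and ground truth must align per image")
    classes = sorted({a.class_id for gt in ground_truth for a in gt})
    ap_table = np.full((len(classes), len(IOU_THRESHOLDS)), np.nan)
    tp50 = fp50 = n_gt_total = 0
    for ci, c in enumerate(classes):
        dets = [(img, d.confidence, np.asarray(d.corners()))
                for img, dd in enumerate(detections) for d in dd if d.class_id == c]
        gts = [np.asarray([a.corners() for a in gt if a.class_id == c]).reshape(-1, 4)
               for gt in ground_truth]
        n_gt = sum(len(g) for g in gts)
        n_gt_total += n_gt
        for ti, t in enumerate(IOU_THRESHOLDS):
            ap_table[ci, ti] = _ap_single(_match_class(dets, gts, t), n_gt)
        # fixed-threshold counts at IoU 0.5
        strong = [d for d in dets if d[1] >= conf_thresh]
        flags = _match_class(strong, gts, 0.50)
        tp50 += int(flags.sum())
        fp50 += int(len(flags) - flags.sum())
    valid = ~np.isnan(ap_table[:, 0])
    map50 = float(np.mean(ap_table[valid, 0])) if valid.any() else 0.0
    map50_95 = float(np.mean(ap_table[valid].mean(axis=1))) if valid.any() else 0.0
    precision = tp50 / (tp50 + fp50) if (tp50 + fp50) else 0.0
    recall = tp50 / n_gt_total if n_gt_total else 0.0
    return EvalResult(float(precision), float(recall), map50, map50_95)


# ---------------------------------------------------------------------------
# target assignment and loss


def assign_targets(annotations: Sequence[Sequence[BoxAnnotation]],
                   grid_sizes: Sequence[Tuple[int, int]],
                   strides=(8, 16, 32), reg_max: int = 16,
                   centre_radius: float = 1.5):
    """Centre-based positive assignment.

    Each ground-truth box picks the level whose stride makes its longer
    side closest to four cells, then marks cells within
    ``centre_radius`` cells of its centre (and inside the box) positive.
    Returns per-level lists of (batch, cell_y, cell_x, class, ltrb_cells).
    """
    img_h = grid_sizes[0][0] * strides[0]
    img_w = grid_sizes[0][1] * strides[0]
    per_level = [[] for _ in strides]
    for b, anns in enumerate(annotations):
        for a in anns:
            side = max(a.w * img_w, a.h * img_h)
            lvl = int(np.argmin([abs(np.log2(max(side, 1e-6) / (4 * s))) for s in strides]))
            s = strides[lvl]
            H, W = grid_sizes[lvl]
            gx, gy = a.cx * img_w / s, a.cy * img_h / s
            x0, y0, x1, y1 = (a.cx - a.w / 2) * img_w / s, (a.cy - a.h / 2) * img_h / s, \
                             (a.cx + a.w / 2) * img_w / s, (a.cy + a.h / 2) * img_h / s
            ry = range(max(0, int(gy - centre_radius)), min(H, int(gy + centre_radius) + 1))
            rx = range(max(0, int(gx - centre_radius)), min(W, int(gx + centre_radius) + 1))
            for iy in ry:
                for ix in rx:
                    cyc, cxc = iy + 0.5, ix + 0.5
                    if abs(cyc - gy) > centre_radius or abs(cxc - gx) > centre_radius:
                        continue
                    ltrb = (cxc - x0, cyc - y0, x1 - cxc, y1 - cyc)
                    if min(ltrb) <= 0.01:
                        continue
                    ltrb = tuple(min(v, reg_max - 1 - 1e-3) for v in ltrb)
                    per_level[lvl].append((b, iy, ix, a.class_id, ltrb))
    return per_level


def _focal_bce(logits, targets, gamma: float):
    p = 1.0 / (1.0 + anp.exp(-logits))
    pt = targets * p + (1 - targets) * (1 - p)
    w = (1 - pt) ** gamma
    eps = 1e-9
    ce = -(targets * anp.log(p + eps) + (1 - targets) * anp.log(1 - p + eps))
    return w * ce


def detection_loss(model: DetectionModel, params, images,
                   annotations: Sequence[Sequence[BoxAnnotation]],
                   cfg: TrainConfig):
    """Composite loss (scalar) for a batch of BCHW images."""
    outputs = model.forward(images, params)
    reg_max = model.cfg.reg_max
    nc = model.cfg.num_classes
    grid_sizes = [getval(o[0]).shape[2:] for o in outputs]
    targets = assign_targets(annotations, grid_sizes, model.strides, reg_max)
    total_cls = 0.0
    total_box = 0.0
    total_dfl = 0.0
    n_pos = 0
    n_cells = 0
    for lvl, ((box_map, cls_map), tgt) in enumerate(zip(outputs, targets)):
        B = getval(cls_map).shape[0]
        H, W = grid_sizes[lvl]
        n_cells += B * nc * H * W
        cls_target = np.zeros((B, nc, H, W))
        for (b, iy, ix, cid, _l) in tgt:
            cls_target[b, cid, iy, ix] = 1.0
        total_cls = total_cls + anp.sum(_focal_bce(cls_map, cls_target, cfg.focal_gamma))
        if not tgt:
            continue
        bi = np.array([t[0] for t in tgt])
        yi = np.array([t[1] for t in tgt])
        xi = np.array([t[2] for t in tgt])
        ltrb_t = np.array([t[4] for t in tgt])  # (P,4) cells
        n_pos += len(tgt)
        box_flat = anp.reshape(box_map, (B, 4, reg_max, H, W))
        logits = box_flat[bi, :, :, yi, xi]  # (P,4,reg_max)
        prob = F.softmax(logits, axis=-1)
        d_pred = anp.sum(prob * np.arange(reg_max)[None, None, :], axis=-1)  # (P,4)
        # GIoU in cell units of this level
        cxc, cyc = xi + 0.5, yi + 0.5
        px0, py0 = cxc - d_pred[:, 0], cyc - d_pred[:, 1]
        px1, py1 = cxc + d_pred[:, 2], cyc + d_pred[:, 3]
        tx0, ty0 = cxc - ltrb_t[:, 0], cyc - ltrb_t[:, 1]
        tx1, ty1 = cxc + ltrb_t[:, 2], cyc + ltrb_t[:, 3]
        iw = anp.maximum(anp.minimum(px1, tx1) - anp.maximum(px0, tx0), 0.0)
        ih = anp.maximum(anp.minimum(py1, ty1) - anp.maximum(py0, ty0), 0.0)
        inter = iw * ih
        union = ((px1 - px0) * (py1 - py0) + (tx1 - tx0) * (ty1 - ty0) - inter)
        iou = inter / (union + 1e-9)
        ew = anp.maximum(px1, tx1) - anp.minimum(px0, tx0)
        eh = anp.maximum(py1, ty1) - anp.minimum(py0, ty0)
        encl = ew * eh + 1e-9
        giou = iou - (encl - union) / encl
        total_box = total_box + anp.sum(1.0 - giou)
        # distribution-focal: cross-entropy on the two neighbouring bins
        lo = np.floor(ltrb_t).astype(int)
        hi = np.minimum(lo + 1, reg_max - 1)
        w_hi = ltrb_t - lo
        w_lo = 1.0 - w_hi
        logp = anp.log(prob + 1e-9)
        pidx = np.arange(len(tgt))[:, None]
        sidx = np.arange(4)[None, :]
        total_dfl = total_dfl - anp.sum(w_lo * logp[pidx, sidx, lo]
                                        + w_hi * logp[pidx, sidx, hi])
    cls_loss = total_cls / max(n_pos, 1)
    box_loss = total_box / max(n_pos, 1)
    dfl_loss = total_dfl / max(n_pos * 4, 1)
    return cfg.cls_weight * cls_loss + cfg.box_weight * box_loss + cfg.dfl_weight * dfl_loss


# ---------------------------------------------------------------------------
# training loop


def smoke_train(model: DetectionModel, dataset, cfg: TrainConfig,
                steps: Optional[int] = None, log=sys.stderr) -> List[float]:
    """SGD-with-momentum training on an in-memory dataset of
    (image HWC float, annotations) pairs; returns the per-step loss trace.

    ``steps`` caps the number of optimizer steps; otherwise
    ``cfg.epochs`` full passes are run.  Aborts on divergence.
    """
    n = len(dataset)
    order_rng = np.random.default_rng(cfg.seed + 1)
    params = model.state()
    flat, unflatten = flatten(params)
    velocity = np.zeros_like(flat)
    model.set_training(True)

    def batch_loss(ptree, idx):
        imgs = np.stack([np.transpose(dataset[i][0], (2, 0, 1)) for i in idx])
        anns = [dataset[i][1] for i in idx]
        return detection_loss(model, ptree, imgs, anns, cfg)

    vag_fn = autograd.value_and_grad(lambda p_flat, idx: batch_loss(unflatten(p_flat), idx))

    trace: List[float] = []
    step = 0
    max_steps = steps if steps is not None else cfg.epochs * max(n // cfg.batch_size, 1)
    while step < max_steps:
        order = order_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            if step >= max_steps:
                break
            idx = order[start : start + cfg.batch_size]
            loss_val, g = vag_fn(flat, idx)
            loss_f = float(getval(loss_val))
            if not np.isfinite(loss_f) or not np.all(np.isfinite(g)):
                raise RuntimeError(f"training diverged at step {step} (loss={loss_f})")
            lr = cfg.lr * min(1.0, (step + 1) / max(cfg.warmup_steps, 1))
            velocity = cfg.momentum * velocity - lr * g
            flat = flat + velocity
            trace.append(loss_f)
            if log is not None:
                print(f"step {step:4d} loss {loss_f:.4f} lr {lr:.4f}", file=log)
            step += 1
    model.load_state(unflatten(flat))
    model.set_training(False)
    return trace


def predict(model: DetectionModel, images, conf_thresh=0.25, iou_thresh=0.45):
    """Run inference on a stack of HWC images; returns detection lists."""
    x = np.stack([np.transpose(im, (2, 0, 1)) for im in images])
    model.set_training(False)
    outputs = model(x)
    return decode_predictions(outputs, model.strides, model.cfg.reg_max,
                              conf_thresh, iou_thresh)
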