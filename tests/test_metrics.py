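"""Detection and counting metric tests, including an independent
COCO-protocol mAP oracle implemented from scratch in this file."""
import numpy as np
import pytest

from lgwheatnet.metrics import (average_precision, confusion_matrix,
                                counting_metrics, map_suite, match_detections)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_match_exact_hit():
    tp, sc, fn = match_detections([[0, 0, 10, 10]], [0.9], [[0, 0, 10, 10]])
    assert tp.tolist() == [True] and fn == 0


def test_match_two_dets_one_gt():
    """Both detections overlap the single GT; only the more confident is TP."""
    tp, sc, fn = match_detections([[0, 0, 10, 10], [1, 1, 11, 11]],
                                  [0.8, 0.9], [[0, 0, 10, 10]])
    assert sc.tolist() == [0.9, 0.8]
    assert tp.tolist() == [True, False]
    assert fn == 0


def test_match_greedy_agrees_with_optimal_small():
    """Greedy matching equals the exhaustive optimal assignment for up to
    3x3 det/gt sets except on documented greedy ties."""
    from itertools import permutations
    rng = np.random.default_rng(0)
    for _ in range(200):
        nd, ng = rng.integers(1, 4), rng.integers(1, 4)
        db = rng.uniform(0, 40, (nd, 2))
        db = np.hstack([db, db + rng.uniform(5, 15, (nd, 2))])
        gb = rng.uniform(0, 40, (ng, 2))
        gb = np.hstack([gb, gb + rng.uniform(5, 15, (ng, 2))])
        sc = rng.uniform(0.1, 1.0, nd)
        tp, _, fn = match_detections(db, sc, gb, 0.5)
        greedy_tp = int(tp.sum())
        # optimal: maximize number of matches with IoU >= .5 over assignments
        from lgwheatnet.loss_assign import iou_matrix
        m = iou_matrix(db, gb) >= 0.5
        best = 0
        for perm in permutations(range(ng)):
            tot = sum(1 for i in range(min(nd, ng)) if i < nd and perm[i] < ng
                      and m[i, perm[i]])
            best = max(best, tot)
        for perm in permutations(range(nd)):
            tot = sum(1 for j in range(min(nd, ng)) if m[perm[j], j])
            best = max(best, tot)
        assert greedy_tp <= best
        # greedy matches at most one det per gt
        assert greedy_tp <= ng


def test_match_wrong_class_is_fp_and_fn():
    """Matching is per class: a det of the wrong class never matches, leaving
    one FP (its own class) and one FN (the GT class)."""
    det_box = np.array([[0, 0, 10, 10.0]])
    gt_box = np.array([[0, 0, 10, 10.0]])
    # detection of class 1 scored against class-0 ground truth
    tp, _, fn = match_detections(det_box, [0.9], np.zeros((0, 4)))  # class-1 gts: none
    assert tp.tolist() == [False]
    tp0, _, fn0 = match_detections(np.zeros((0, 4)), [], gt_box)    # class-0 dets: none
    assert fn0 == 1


# ---------------------------------------------------------------------------
# AP
# ---------------------------------------------------------------------------

def test_ap_hand_example():
    """TP,FP,TP at conf .9/.8/.7 with 2 GT: envelope area = 1*0.5 + 2/3*0.5."""
    ap = average_precision(np.array([True, False, True]), 2)
    assert ap == pytest.approx(1 * 0.5 + (2 / 3) * 0.5, abs=1e-9)


def test_ap_degenerate_cases():
    assert average_precision(np.array([True]), 1) == 1.0
    assert average_precision(np.zeros(0, dtype=bool), 3) == 0.0
    assert np.isnan(average_precision(np.array([True]), 0))


# ---------------------------------------------------------------------------
# independent COCO-protocol oracle
# ---------------------------------------------------------------------------

def _oracle_ap(det_entries, gt_boxes_by_img, iou_thr):
    """Reference AP, written independently: explicit greedy matching followed
    by O(n^2) all-point envelope integration."""
    det_entries = sorted(det_entries, key=lambda e: -e[0])
    used = {img: np.zeros(len(b), dtype=bool) for img, b in gt_boxes_by_img.items()}
    n_gt = sum(len(b) for b in gt_boxes_by_img.values())
    flags = []
    for score, img, box in det_entries:
        gb = gt_boxes_by_img[img]
        best, bj = 0.0, -1
        for j, g in enumerate(gb):
            if used[img][j]:
                continue
            ix = max(0, min(box[2], g[2]) - max(box[0], g[0]))
            iy = max(0, min(box[3], g[3]) - max(box[1], g[1]))
            inter = ix * iy
            union = ((box[2] - box[0]) * (box[3] - box[1])
                     + (g[2] - g[0]) * (g[3] - g[1]) - inter)
            ov = inter / union if union > 0 else 0.0
            if ov >= iou_thr and ov > best:
                best, bj = ov, j
        if bj >= 0:
            used[img][bj] = True
            flags.append(1)
        else:
            flags.append(0)
    if n_gt == 0:
        return float("nan")
    precisions, recalls = [], []
    tp = fp = 0
    for f in flags:
        tp += f
        fp += 1 - f
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_gt)
    ap, prev_r = 0.0, 0.0
    for k in range(len(flags)):
        if flags[k]:
            r = recalls[k]
            p_max = max(precisions[k:])  # envelope: best precision at >= r
            ap += (r - prev_r) * p_max
            prev_r = r
    return ap


def _synthetic_benchmark(seed=0, n_images=12):
    rng = np.random.default_rng(seed)
    dets, gts = [], []
    for _ in range(n_images):
        ng = rng.integers(2, 7)
        gb = rng.uniform(0, 200, (ng, 2))
        gb = np.hstack([gb, gb + rng.uniform(15, 40, (ng, 2))])
        gc = rng.integers(0, 3, ng)
        db, ds, dc = [], [], []
        for j in range(ng):
            if rng.random() < 0.85:  # true positive with jitter
                jit = rng.normal(0, 3, 4)
                db.append(gb[j] + jit)
                ds.append(rng.uniform(0.4, 1.0))
                dc.append(gc[j])
        for _ in range(rng.integers(0, 4)):  # false positives
            c = rng.uniform(0, 200, 2)
            db.append(np.concatenate([c, c + rng.uniform(15, 40, 2)]))
            ds.append(rng.uniform(0.05, 0.7))
            dc.append(rng.integers(0, 3))
        dets.append((np.array(db).reshape(-1, 4), np.array(ds),
                     np.array(dc, dtype=int)))
        gts.append((gb, gc))
    return dets, gts


def test_map_standard10_matches_independent_oracle():
    """map50 and map50-95 (standard 10-threshold protocol) agree with the
    from-scratch reference implementation to 1e-6 on a fixed benchmark."""
    dets, gts = _synthetic_benchmark(3)
    res = map_suite(dets, gts, mode="standard10")
    aps = {}
    for t in np.arange(0.50, 0.96, 0.05):
        per_class = []
        for k in range(3):
            entries, gt_by_img = [], {}
            for img, ((db, ds, dc), (gb, gc)) in enumerate(zip(dets, gts)):
                gt_by_img[img] = [g for g, c in zip(gb, gc) if c == k]
                for bx, s, c in zip(db, ds, dc):
                    if c == k:
                        entries.append((s, img, bx))
            per_class.append(_oracle_ap(entries, gt_by_img, float(t)))
        aps[round(float(t), 2)] = per_class
    o_map50 = np.nanmean(aps[0.5])
    o_map5095 = np.nanmean(np.nanmean(list(aps.values()), axis=0))
    assert res["map50"] == pytest.approx(o_map50, abs=1e-6)
    assert res["map50_95"] == pytest.approx(o_map5095, abs=1e-6)


def test_map_suite_perfect_detector_and_protocols():
    gts = []
    rng = np.random.default_rng(1)
    for _ in range(5):
        gb = rng.uniform(0, 100, (4, 2))
        gb = np.hstack([gb, gb + 20])
        gts.append((gb, rng.integers(0, 3, 4)))
    dets = [(gb.copy(), np.full(len(gb), 0.9), gc.copy()) for gb, gc in gts]
    for mode in ("standard10", "paper91"):
        res = map_suite(dets, gts, mode=mode)
        assert res["precision"] == 1.0 and res["recall"] == 1.0
        assert res["map50"] == pytest.approx(1.0)
        assert res["map50_95"] == pytest.approx(1.0)


def test_map5095_not_above_map50_and_protocols_close():
    dets, gts = _synthetic_benchmark(7)
    r10 = map_suite(dets, gts, mode="standard10")
    r91 = map_suite(dets, gts, mode="paper91")
    for r in (r10, r91):
        assert r["map50_95"] <= r["map50"] + 1e-12
        assert 0 <= r["precision"] <= 1 and 0 <= r["recall"] <= 1
    assert abs(r10["map50_95"] - r91["map50_95"]) < 0.02
    assert r10["map50"] == pytest.approx(r91["map50"])


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_perfect_and_empty():
    gts = [(np.array([[0, 0, 10, 10.0], [20, 20, 30, 30.0]]), np.array([0, 2]))]
    dets_perfect = [(gts[0][0].copy(), np.array([0.9, 0.9]), np.array([0, 2]))]
    m = confusion_matrix(dets_perfect, gts)
    assert m[0, 0] == 1.0 and m[2, 2] == 1.0
    dets_none = [(np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=int))]
    m2 = confusion_matrix(dets_none, gts)
    assert m2[3, 0] == 0.5 and m2[3, 2] == 0.5  # all GT mass in background row


def test_confusion_cross_class():
    gts = [(np.array([[0, 0, 10, 10.0]]), np.array([1]))]
    dets = [(np.array([[0, 0, 10, 10.0]]), np.array([0.9]), np.array([0]))]
    m = confusion_matrix(dets, gts, num_classes=2)
    assert m[0, 1] == 1.0


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_counting_perfect():
    cm = counting_metrics([3, 5, 7], [3, 5, 7])
    assert (cm.rmse, cm.mae, cm.mse) == (0, 0, 0) and cm.r2 == 1.0


def test_counting_constant_offset():
    """Unit offset gives unit errors but perfect correlation: the R^2 form is
    bias-insensitive."""
    cm = counting_metrics([1, 2, 3], [2, 3, 4])
    assert cm.rmse == pytest.approx(1.0)
    assert cm.mae == pytest.approx(1.0)
    assert cm.mse == pytest.approx(1.0)
    assert cm.r2 == pytest.approx(1.0)


def test_counting_rmse_squared_is_mse(rng):
    t = rng.integers(0, 30, 40)
    p = np.clip(t + rng.integers(-4, 5, 40), 0, None)
    cm = counting_metrics(t, p)
    assert cm.rmse ** 2 == pytest.approx(cm.mse, rel=1e-12)


def test_counting_zero_variance_warns():
    with pytest.warns(UserWarning):
        cm = counting_metrics([4, 4, 4], [3, 5, 4])
    assert cm.r2 == 0.0
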