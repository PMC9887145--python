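"""Grey-level co-occurrence matrix (GLCM) texture features.

Eight Haralick-style statistics are computed from the symmetric, normalised
GLCM of a sliding window (default 7×7) at a fixed pixel offset: MEAN, VAR,
HOM (homogeneity), CON (contrast), DIS (dissimilarity), ENT (entropy, natural
log), ASM (angular second moment) and COR (correlation). The input band is
first quantised to N grey levels (equal-width bins over its valid range).

A co-occurrence is counted when both pixels of the offset pair lie inside the
window (and are valid); windows are truncated at image edges. The GLCM is
symmetrised before normalisation, so MEAN and VAR along rows and columns
coincide and a single value per statistic is reported.
"""

from __future__ import annotations

import numpy as np

from .errors import FeatureError

FEATURE_NAMES = ("MEAN", "VAR", "HOM", "CON", "DIS", "ENT", "ASM", "COR")
DEFAULT_WINDOW = 7
DEFAULT_LEVELS = 64
DEFAULT_OFFSET = (1, 1)
_VAR_EPS = 1e-12


def quantize(
    band: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    valid_mask: np.ndarray | None = None,
    vrange: tuple[float, float] | None = None,
) -> np.ndarray:
    """Quantise a band to integer grey levels 0…levels−1 (equal-width bins)."""
    if levels < 2:
        raise FeatureError(f"need at least 2 grey levels, got {levels}")
    band = np.asarray(band, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(band)
    if vrange is None:
        vals = band[valid_mask]
        if vals.size == 0:
            raise FeatureError("no valid pixels to quantise")
        lo, hi = float(np.min(vals)), float(np.max(vals))
    else:
        lo, hi = vrange
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.int64)
    q = np.floor((band - lo) / (hi - lo) * levels)
    return np.clip(np.nan_to_num(q, nan=0.0), 0, levels - 1).astype(np.int64)


def _features_from_probs(i: np.ndarray, j: np.ndarray, p: np.ndarray) -> dict[str, float]:
    """Evaluate the eight statistics from the nonzero GLCM entries."""
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum(p * (i - mu_i) ** 2))
    var_j = float(np.sum(p * (j - mu_j) ** 2))
    d = i - j
    if var_i < _VAR_EPS or var_j < _VAR_EPS:
        cor = 1.0  # degenerate window: a single grey level is perfectly correlated
    else:
        cor = float(np.sum(p * (i - mu_i) * (j - mu_j)) / np.sqrt(var_i * var_j))
    return {
        "MEAN": mu_i,
        "VAR": var_i,
        "HOM": float(np.sum(p / (1.0 + d**2))),
        "CON": float(np.sum(p * d**2)),
        "DIS": float(np.sum(p * np.abs(d))),
        "ENT": float(np.sum(-p * np.log(p))),
        "ASM": float(np.sum(p**2)),
        "COR": cor,
    }


def _pair_codes(img: np.ndarray, offset: tuple[int, int], valid: np.ndarray, levels: int):
    """Symmetric pair codes i*levels+j on a grid of pair *start* positions.

    Entry (r, c) describes the pair (r, c) ↔ (r+dr, c+dc); −1 marks pairs with
    an invalid endpoint. Offsets are normalised so dr ≥ 0 (symmetry).
    """
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise FeatureError("offset (0, 0) is not a displacement")
    if dr < 0 or (dr == 0 and dc < 0):
        dr, dc = -dr, -dc
    R, C = img.shape
    if dr >= R or abs(dc) >= C:
        raise FeatureError(f"offset {offset} larger than image {img.shape}")
    if dc >= 0:
        a = img[: R - dr, : C - dc]
        b = img[dr:, dc:]
        va = valid[: R - dr, : C - dc] & valid[dr:, dc:]
        origin = (0, 0)
    else:
        a = img[: R - dr, -dc:]
        b = img[dr:, :dc]
        va = valid[: R - dr, -dc:] & valid[dr:, :dc]
        origin = (0, -dc)  # start pixel column index of pair grid cell (0,0)
    codes = np.where(va, a * levels + b, -1)
    return codes, (dr, dc), origin


def glcm_features_region(
    img: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    valid_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """GLCM statistics of a whole region (single co-occurrence matrix)."""
    img = np.asarray(img)
    if valid_mask is None:
        valid_mask = np.ones(img.shape, dtype=bool)
    codes, _, _ = _pair_codes(img, offset, valid_mask, levels)
    flat = codes[codes >= 0]
    if flat.size == 0:
        raise FeatureError("no valid co-occurrence pairs in region")
    counts = np.bincount(flat, minlength=levels * levels).astype(float)
    counts = counts.reshape(levels, levels)
    counts = counts + counts.T  # symmetrise
    p = counts / counts.sum()
    ii, jj = np.nonzero(p)
    return _features_from_probs(ii.astype(float), jj.astype(float), p[ii, jj])


def glcm_feature_maps(
    img: np.ndarray,
    window: int = DEFAULT_WINDOW,
    levels: int = DEFAULT_LEVELS,
    offset: tuple[int, int] = DEFAULT_OFFSET,
    valid_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel GLCM statistics over a sliding window (truncated at edges).

    Pixels whose window contains no valid pair get NaN in every map.
    """
    img = np.asarray(img)
    if window < 1 or window % 2 == 0:
        raise FeatureError(f"window must be odd and positive, got {window}")
    R, C = img.shape
    if window > max(R, C) * 2:
        raise FeatureError(f"window {window} larger than image {img.shape}")
    if levels < 2:
        raise FeatureError(f"need at least 2 grey levels, got {levels}")
    if valid_mask is None:
        valid_mask = np.ones(img.shape, dtype=bool)

    codes, (dr, dc), (orow, ocol) = _pair_codes(img, offset, valid_mask, levels)
    pr_max, pc_max = codes.shape
    half = window // 2
    nbins = levels * levels
    maps = {name: np.full((R, C), np.nan) for name in FEATURE_NAMES}

    for r in range(R):
        # pair (pr, pc) occupies pixels rows pr..pr+dr, cols (pc+ocol)..(pc+ocol+dc)
        w_r0, w_r1 = max(r - half, 0), min(r + half, R - 1)
        pr0, pr1 = w_r0, min(w_r1 - dr, pr_max - 1)
        if pr1 < pr0:
            continue
        for c in range(C):
            if not valid_mask[r, c]:
                continue
            w_c0, w_c1 = max(c - half, 0), min(c + half, C - 1)
            # both endpoints' columns must lie inside [w_c0, w_c1]
            pc0 = max(w_c0 - ocol, w_c0 - ocol - dc if dc < 0 else w_c0 - ocol)
            pc0 = max(pc0, 0)
            pc1 = min(w_c1 - ocol - dc, w_c1 - ocol) if dc >= 0 else min(
                w_c1 - ocol, w_c1 - ocol - dc
            )
            pc1 = min(pc1, pc_max - 1)
            if pc1 < pc0:
                continue
            block = codes[pr0 : pr1 + 1, pc0 : pc1 + 1].ravel()
            block = block[block >= 0]
            if block.size == 0:
                continue
            counts = np.bincount(block, minlength=nbins).astype(float)
            counts = counts.reshape(levels, levels)
            counts = counts + counts.T
            p = counts / counts.sum()
            ii, jj = np.nonzero(p)
            feats = _features_from_probs(ii.astype(float), jj.astype(float), p[ii, jj])
            for name, val in feats.items():
                maps[name][r, c] = val
    return maps
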