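"""Zhang-Suen two-subiteration thinning.

Reduces a binary mask to a one-pixel-wide skeleton by repeatedly deleting
boundary pixels in two alternating subpasses until a fixpoint.  For a pixel
p with 8-neighbors p2..p9 (clockwise from north), with B(p) the foreground
neighbor count and A(p) the number of 0->1 transitions in the ordered cycle
p2,p3,...,p9,p2:

* subpass 1 deletes p iff 2 <= B <= 6, A == 1, p2*p4*p6 == 0 and p4*p6*p8 == 0;
* subpass 2 deletes p iff 2 <= B <= 6, A == 1, p2*p4*p8 == 0 and p2*p6*p8 == 0.

Deletions within a subpass are applied simultaneously.  The image border is
treated as background (implicit background frame).

The classic algorithm terminates with two kinds of staircase residue: an
occasional fully-set 2x2 block (violating the one-pixel-width contract) and
two-pixel diagonal steps whose corner pixels carry three raw neighbors,
which downstream branch analysis would mistake for junctions.  A final
deterministic cleanup therefore deletes, in repeated (row, col) scans,
every foreground pixel that is *simple* — its foreground neighbors remain
mutually 8-connected without it — and is not an endpoint, until a fixpoint.
This removes exactly the redundant corner/block pixels (a mid-chain pixel
of a minimal curve is never simple, and true junction pixels have
neighbors in >= 2 separate groups), preserving connectivity and leaving a
minimal skeleton whose raw neighbor counts reflect topology.  A last guard
re-seeds any mask component the iteration erased outright (an isolated
fully-set 2x2 block is deleted in one pass, and small round blobs can
erode to that state) with a single pixel at its most interior point, so
the component count is preserved.  An optional spur-pruning pass (terminal
branches up to a given length removed; off by default) is provided because
noise spurs otherwise inflate branch counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import BinaryMask


@dataclass
class SkeletonImage:
    """One-pixel-wide binary skeleton aligned to its source mask."""

    pixels: np.ndarray
    source_mask_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            raise TypeError("SkeletonImage pixels must be boolean")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def _neighbor_planes(padded: np.ndarray):
    """p2..p9 clockwise from north, as views into the padded array."""
    return (
        padded[:-2, 1:-1],  # p2 N
        padded[:-2, 2:],    # p3 NE
        padded[1:-1, 2:],   # p4 E
        padded[2:, 2:],     # p5 SE
        padded[2:, 1:-1],   # p6 S
        padded[2:, :-2],    # p7 SW
        padded[1:-1, :-2],  # p8 W
        padded[:-2, :-2],   # p9 NW
    )


def _subpass(img: np.ndarray, first: bool) -> bool:
    """Apply one subpass in place; return True if any pixel was deleted."""
    padded = np.pad(img, 1, constant_values=False)
    p2, p3, p4, p5, p6, p7, p8, p9 = _neighbor_planes(padded)
    cycle = (p2, p3, p4, p5, p6, p7, p8, p9, p2)
    b = sum(n.astype(np.uint8) for n in cycle[:-1])
    a = sum((~x & y) for x, y in zip(cycle[:-1], cycle[1:]))
    cond = img & (b >= 2) & (b <= 6) & (a == 1)
    if first:
        cond &= ~(p2 & p4 & p6) & ~(p4 & p6 & p8)
    else:
        cond &= ~(p2 & p4 & p8) & ~(p2 & p6 & p8)
    if not cond.any():
        return False
    img[cond] = False
    return True


def zhang_suen_thin(mask: BinaryMask, prune: int = 0) -> SkeletonImage:
    """Thin a binary mask to a 1-px-wide skeleton (Zhang & Suen's method).

    Parameters
    ----------
    mask : BinaryMask
        Boolean foreground mask.
    prune : int
        If > 0, remove terminal spurs of up to this many pixels after
        thinning (default 0: no pruning).
    """
    pixels = np.asarray(getattr(mask, "pixels", mask))
    if pixels.dtype != bool:
        raise TypeError("zhang_suen_thin requires a boolean mask")
    img = pixels.copy()
    while True:
        changed = _subpass(img, first=True)
        changed |= _subpass(img, first=False)
        if not changed:
            break
    _remove_redundant_pixels(img)
    for _ in range(4):  # block repair may expose new redundancy
        if not _repair_junction_blocks(img, pixels):
            break
        _remove_redundant_pixels(img)
    _restore_lost_components(img, pixels)
    if prune > 0:
        img = prune_spurs(img, prune)
    return SkeletonImage(pixels=img, source_mask_id=getattr(mask, "source_id", ""))


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
def _is_simple(img: np.ndarray, r: int, c: int) -> bool:
    """True if deleting (r, c) keeps its foreground neighbors 8-connected
    to each other within the 3x3 neighborhood (a local simple-point test)."""
    h, w = img.shape
    nbrs = [
        (r + dr, c + dc)
        for dr, dc in _OFFSETS
        if 0 <= r + dr < h and 0 <= c + dc < w and img[r + dr, c + dc]
    ]
    if len(nbrs) < 2:
        return False  # endpoint or isolated: never delete
    seen = {nbrs[0]}
    stack = [nbrs[0]]
    pool = set(nbrs)
    while stack:
        a = stack.pop()
        for b in pool - seen:
            if abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1:
                seen.add(b)
                stack.append(b)
    return len(seen) == len(nbrs)


def _remove_redundant_pixels(img: np.ndarray) -> None:
    """Reduce to a minimal skeleton: delete simple non-endpoint pixels.

    Sweeps in (row, col) scan order until a fixpoint.  Deleting a simple
    pixel cannot disconnect the skeleton.  Only pixels with at least three
    neighbors are candidates: that is what removes two-pixel diagonal
    ribbons (which the two-subpass iteration cannot thin), staircase
    corners and 2x2-block residue, while pixels interior to a one-pixel
    chain (two non-adjacent neighbors, not simple) and chain corners
    (two neighbors, protected by the degree floor) are never touched — a
    plain simple-point sweep would cascade along a ribbon and consume
    whole rods.  A second rule collapses "bump" triangles (a pixel whose
    two neighbors are mutually adjacent and one of them carries a third
    neighbor), which otherwise read as spurious junction pairs on a
    diagonal line.  In-place; deterministic.
    """

    def cur_deg(r: int, c: int) -> int:
        return sum(
            img[r + dr, c + dc]
            for dr, dc in _OFFSETS
            if 0 <= r + dr < img.shape[0] and 0 <= c + dc < img.shape[1]
        )

    def fg_nbrs(r: int, c: int):
        return [
            (r + dr, c + dc)
            for dr, dc in _OFFSETS
            if 0 <= r + dr < img.shape[0]
            and 0 <= c + dc < img.shape[1]
            and img[r + dr, c + dc]
        ]

    while True:
        deg = neighbor_count(img)
        deleted = False
        for r, c in np.argwhere(img & (deg >= 3)):
            # re-check on the current image: deletions upstream in this
            # sweep may have reduced this pixel's neighborhood
            if img[r, c] and cur_deg(r, c) >= 3 and _is_simple(img, r, c):
                img[r, c] = False
                deleted = True
        for r, c in np.argwhere(img & (deg == 2)):
            if not img[r, c] or cur_deg(r, c) != 2:
                continue
            (n1, n2) = fg_nbrs(r, c)
            if (
                abs(n1[0] - n2[0]) <= 1
                and abs(n1[1] - n2[1]) <= 1
                and (cur_deg(*n1) >= 3 or cur_deg(*n2) >= 3)
            ):
                img[r, c] = False
                deleted = True
        if not deleted:
            return


def neighbor_count(skel: np.ndarray) -> np.ndarray:
    """Per-pixel count of foreground 8-neighbors (0 off the skeleton)."""
    padded = np.pad(skel, 1, constant_values=False)
    b = sum(n.astype(np.uint8) for n in _neighbor_planes(padded))
    return np.where(skel, b, 0)


def _restore_lost_components(img: np.ndarray, mask: np.ndarray) -> None:
    """Re-seed mask components the thinning erased entirely.

    The two-subpass iteration deletes an isolated fully-set 2x2 block in
    one pass, and small round blobs can erode down to such a block and
    vanish; a skeleton must keep one component per mask component, so each
    lost component is restored as a single pixel at its most interior
    point (distance-transform argmax, first in scan order).  In-place.
    """
    from scipy import ndimage as ndi

    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return
    survived = np.unique(labels[img])
    lost = set(range(1, n + 1)) - set(int(v) for v in survived)
    for lbl in lost:
        sel = labels == lbl
        rows, cols = np.nonzero(sel)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        patch = sel[r0:r1, c0:c1]
        dist = ndi.distance_transform_edt(np.pad(patch, 1))[1:-1, 1:-1]
        r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
        img[r0 + r, c0 + c] = True


def _repair_junction_blocks(img: np.ndarray, mask: np.ndarray) -> bool:
    """Rectify irreducible 2x2 junction blocks left by an X-type crossing.

    Where four strands attach diagonally to a fully-set 2x2 block, no
    single pixel is deletable without disconnecting a strand.  The block is
    resolved by deleting one diagonal pair and reconnecting each orphaned
    strand through an "elbow" pixel taken from the *source mask* (so the
    skeleton stays a subset of the mask and topology is preserved).  Blocks
    that cannot be repaired this way are left untouched.  Returns True if
    anything changed.
    """
    h, w = img.shape
    blocks = np.argwhere(img[:-1, :-1] & img[:-1, 1:] & img[1:, :-1] & img[1:, 1:])
    changed = False
    for r, c in blocks:
        quad = [(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)]
        if not all(img[p] for p in quad):
            continue  # already altered by an earlier repair
        for keep, drop in (
            ([(r, c), (r + 1, c + 1)], [(r, c + 1), (r + 1, c)]),
            ([(r, c + 1), (r + 1, c)], [(r, c), (r + 1, c + 1)]),
        ):
            orphans = []
            for d in drop:
                for dr, dc in _OFFSETS:
                    n = (d[0] + dr, d[1] + dc)
                    if not (0 <= n[0] < h and 0 <= n[1] < w):
                        continue
                    if n in quad or not img[n]:
                        continue
                    if not any(
                        abs(n[0] - k[0]) <= 1 and abs(n[1] - k[1]) <= 1 for k in keep
                    ):
                        orphans.append(n)
            elbows = []
            ok = True
            for o in orphans:
                found = None
                for dr, dc in _OFFSETS:
                    q = (o[0] + dr, o[1] + dc)
                    if not (0 <= q[0] < h and 0 <= q[1] < w):
                        continue
                    if img[q] or not mask[q] or q in drop:
                        continue
                    if any(
                        abs(q[0] - k[0]) <= 1 and abs(q[1] - k[1]) <= 1 for k in keep
                    ):
                        found = q
                        break
                if found is None:
                    ok = False
                    break
                elbows.append(found)
            if ok:
                for d in drop:
                    img[d] = False
                for q in elbows:
                    img[q] = True
                changed = True
                break
    return changed


def prune_spurs(skel: np.ndarray, max_length: int) -> np.ndarray:
    """Remove terminal branches of at most ``max_length`` pixels.

    A spur is the chain of pixels walked from an endpoint (1 neighbor)
    through degree-2 pixels; it is deleted only if a junction (>= 3
    neighbors) is reached within ``max_length`` steps, so whole rods are
    never consumed.
    """
    out = skel.copy()
    deg = neighbor_count(out)
    endpoints = np.argwhere(out & (deg == 1))
    fg = {tuple(p) for p in np.argwhere(out)}
    for ep in map(tuple, endpoints):
        if ep not in fg:
            continue
        path = [ep]
        prev, cur = None, ep
        hit_junction = False
        while len(path) <= max_length:
            nbrs = [
                (cur[0] + dr, cur[1] + dc)
                for dr, dc in _OFFSETS
                if (cur[0] + dr, cur[1] + dc) in fg and (cur[0] + dr, cur[1] + dc) != prev
            ]
            junctions = [n for n in nbrs if len(_fg_neighbors(n, fg)) >= 3]
            if junctions:
                hit_junction = True
                break
            if len(nbrs) != 1:
                break  # isolated chain or another endpoint: not a spur
            prev, cur = cur, nbrs[0]
            path.append(cur)
        if hit_junction:
            for p in path:
                fg.discard(p)
                out[p] = False
    # removing a spur can leave its attachment pixel as a redundant bump
    _remove_redundant_pixels(out)
    return out


def _fg_neighbors(p, fg):
    return [(p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS if (p[0] + dr, p[1] + dc) in fg]
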