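import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the package internals

def flood_components(mask):
    """8-connected components by explicit stack-based flood fill.

    Returns a list of sets of (row, col) tuples.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    ny, nx = mask.shape
    for r0 in range(ny):
        for c0 in range(nx):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < ny and 0 <= cc < nx
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def brute_boundary(mask):
    """Member pixels with a 4-neighbour outside the mask (or frame edge)."""
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    out = set()
    for r in range(ny):
        for c in range(nx):
            if not mask[r, c]:
                continue
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < ny and 0 <= cc < nx) or not mask[rr, cc]:
                    out.add((r, c))
                    break
    return out


def brute_edge_distance(centroid_nm, mask, px):
    """Signed distance via exhaustive scan over brute-force boundary pixels."""
    cy, cx = centroid_nm
    best = min(((r * px - cy) ** 2 + (c * px - cx) ** 2) ** 0.5
               for r, c in brute_boundary(mask))
    r, c = int(round(cy / px)), int(round(cx / px))
    ny, nx = mask.shape
    inside = 0 <= r < ny and 0 <= c < nx and bool(mask[r, c])
    return -best if inside else best


def brute_centroid(frame, mask, px):
    num_y = num_x = tot = 0.0
    for (r, c) in zip(*np.nonzero(mask)):
        w = float(frame[r, c])
        num_y += w * r
        num_x += w * c
        tot += w
    return num_y / tot * px, num_x / tot * px


def gaussian_blob(shape, cy, cx, sigma_px, amplitude):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                              / (2 * sigma_px ** 2))
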