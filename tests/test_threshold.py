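import numpy as np
import pytest

from ciliaquant.errors import (
    DegenerateImageError,
    InvalidInputError,
    InvalidParameterError,
)
from ciliaquant.imagecore import auto_threshold
from ciliaquant.imagecore.threshold import (
    histogram_256,
    minerror_threshold,
    shanbhag_threshold,
    yen_threshold,
)

# ---------------------------------------------------------------------------
# independent plain-loop criterion oracles


def yen_oracle(counts):
    """Exhaustive scan of Yen's maximum-correlation criterion."""
    import math

    total = sum(counts)
    p = [c / total for c in counts]
    occupied = [i for i, c in enumerate(counts) if c]
    lo, hi = occupied[0], occupied[-1]
    best_t, best = lo, -math.inf
    for t in range(lo, hi):  # both classes must be non-empty
        p1 = sum(p[: t + 1])
        p1sq = sum(v * v for v in p[: t + 1])
        p2sq = sum(v * v for v in p[t + 1 :])
        crit = 0.0
        if p1sq * p2sq > 0:
            crit += -math.log(p1sq * p2sq)
        if 0 < p1 < 1:
            crit += 2 * math.log(p1 * (1 - p1))
        if crit > best:
            best, best_t = crit, t
    return best_t


def shanbhag_oracle(counts):
    """Exhaustive scan of Shanbhag's fuzzy-information distance."""
    import math

    total = sum(counts)
    p = [c / total for c in counts]
    P1 = []
    acc = 0.0
    for v in p:
        acc += v
        P1.append(acc)
    P2 = [1.0 - v for v in P1]
    occupied = [i for i, c in enumerate(counts) if c]
    lo, hi = occupied[0], occupied[-1]
    eps = 2.220446049250313e-16
    best_t, best = lo, math.inf
    for t in range(lo, hi + 1):
        if P1[t] < eps or P2[t] < eps:
            continue
        term = 0.5 / P1[t]
        ent_back = -term * sum(
            p[ih] * math.log(1.0 - term * P1[ih - 1]) for ih in range(1, t + 1)
        )
        term = 0.5 / P2[t]
        ent_obj = -term * sum(
            p[ih] * math.log(1.0 - term * P2[ih]) for ih in range(t + 1, 256)
        )
        dist = abs(ent_back - ent_obj)
        if dist < best:
            best, best_t = dist, t
    return best_t


def minerror_oracle(counts, max_iter=100):
    """Independent plain-float reimplementation of the iterated
    Kittler-Illingworth fit started from the histogram mean."""
    import math

    total = sum(counts)
    mean_t = int(round(sum(i * c for i, c in enumerate(counts)) / total))
    occupied = [i for i, c in enumerate(counts) if c]
    lo, hi = occupied[0], occupied[-1]

    t, prev = mean_t, -2
    for _ in range(max_iter):
        if t == prev:
            return t, True
        t = min(max(t, lo), hi - 1)
        b1 = sum(counts[: t + 1])
        b2 = total - b1
        if b1 <= 0 or b2 <= 0:
            return mean_t, False
        mu = sum(i * counts[i] for i in range(t + 1)) / b1
        nu = sum(i * counts[i] for i in range(t + 1, 256)) / b2
        pp = b1 / total
        qq = b2 / total
        sigma2 = sum(i * i * counts[i] for i in range(t + 1)) / b1 - mu * mu
        tau2 = sum(i * i * counts[i] for i in range(t + 1, 256)) / b2 - nu * nu
        if sigma2 <= 0 or tau2 <= 0:
            return mean_t, False
        w0 = 1.0 / sigma2 - 1.0 / tau2
        w1 = mu / sigma2 - nu / tau2
        w2 = mu * mu / sigma2 - nu * nu / tau2 + math.log(
            (sigma2 * qq * qq) / (tau2 * pp * pp)
        )
        sq = w1 * w1 - w0 * w2
        if sq < 0:
            return mean_t, False
        if w0 == 0:
            new_t = 0.5 * (mu + nu) if w1 != 0 else float(t)
        else:
            new_t = (w1 + math.sqrt(sq)) / w0
        if not math.isfinite(new_t):
            return mean_t, False
        prev, t = t, int(round(new_t))
    return mean_t, False


def random_test_image(rng):
    """A random 8-bit image drawn from a two-component Gaussian mixture."""
    n = 48
    mus = rng.uniform(20, 230, size=2)
    sds = rng.uniform(3, 40, size=2)
    w = rng.uniform(0.1, 0.9)
    comp = rng.random((n, n)) < w
    img = np.where(
        comp,
        rng.normal(mus[0], sds[0], (n, n)),
        rng.normal(mus[1], sds[1], (n, n)),
    )
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------


class TestHistogram:
    def test_identity_for_uint8(self, rng):
        img = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        counts, lo, hi, ident = histogram_256(img)
        assert ident and lo == 0.0 and hi == 255.0
        np.testing.assert_array_equal(counts, np.bincount(img.ravel(), minlength=256))

    def test_rescale_for_16bit(self):
        img = np.array([[100, 100], [1000, 1000]], dtype=np.uint16)
        counts, lo, hi, ident = histogram_256(img)
        assert not ident and lo == 100.0 and hi == 1000.0
        assert counts[0] == 2 and counts[255] == 2 and counts.sum() == 4

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateImageError):
            histogram_256(np.full((5, 5), 9))
        with pytest.raises(InvalidInputError):
            histogram_256(np.zeros((0, 5)))


class TestTwoLevelSeparation:
    """A perfectly bimodal image must split exactly for all three methods."""

    @pytest.mark.parametrize("method", ["yen", "shanbhag", "minerror"])
    def test_balanced_two_level(self, method):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[:, 10:] = 200
        img[:, :10] = 10
        mask = auto_threshold(img, method)
        np.testing.assert_array_equal(mask.pixels, img == 200)


class TestOracles:
    def test_yen_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            img = random_test_image(rng)
            counts, *_ = histogram_256(img)
            assert yen_threshold(counts) == yen_oracle(counts.tolist())

    def test_shanbhag_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            img = random_test_image(rng)
            counts, *_ = histogram_256(img)
            assert shanbhag_threshold(counts) == shanbhag_oracle(counts.tolist())

    def test_minerror_matches_fixed_point(self, rng):
        for _ in range(10):
            img = random_test_image(rng)
            counts, *_ = histogram_256(img)
            assert minerror_threshold(counts) == minerror_oracle(counts.tolist())

    def test_minerror_converges_on_bimodal(self, rng):
        img = np.concatenate(
            [rng.normal(40, 8, 2000), rng.normal(200, 10, 2000)]
        )
        img = np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(40, 100)
        t, converged = minerror_threshold(histogram_256(img)[0])
        assert converged and 60 < t < 180


class TestAutoThreshold:
    def test_threshold_value_scale_16bit(self, rng):
        img = (rng.uniform(0, 1, (30, 30)) ** 2 * 4000).astype(np.uint16)
        img[:5, :5] += 20000
        mask = auto_threshold(img, "yen")
        # positives are exactly the pixels above the reported original-scale
        # threshold (bin upper edge)
        assert mask.pixels.sum() > 0
        assert img[mask.pixels].min() >= mask.threshold_value - 1e-6

    def test_unknown_method(self):
        with pytest.raises(InvalidParameterError):
            auto_threshold(np.zeros((4, 4), dtype=np.uint8), "otsu")

    def test_requires_2d(self):
        with pytest.raises(InvalidInputError):
            auto_threshold(np.zeros((2, 4, 4), dtype=np.uint8), "yen")

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            auto_threshold(np.full((8, 8), 3, dtype=np.uint8), "yen")

    def test_minerror_fallback_flagged(self):
        # two zero-variance delta classes defeat the Gaussian fit: the mean
        # threshold fallback applies, with a warning, and still separates
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 200
        mask = auto_threshold(img, "minerror")
        assert mask.warning is not None
        np.testing.assert_array_equal(mask.pixels, img == 200)
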