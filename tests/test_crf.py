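import itertools

import numpy as np
import pytest

from tumorcascade import (
    CrfParams,
    crf_energy,
    crf_refine,
    uncertainty_aware_crf,
    uncertainty_gate,
)
from tumorcascade.errors import FormatError


def enumerate_gibbs_energies(p_fg, image, params):
    """Independent brute-force oracle: Gibbs energy of all 2^n labelings.

    Built from the model definition alone (floored -log unaries; truncated
    Gaussian spatial/appearance Potts pairs), without touching the CRF
    module's internals.  Labeling index = binary code of the flattened
    labeling (most significant bit first).
    """
    shape = np.asarray(p_fg).shape
    n = int(np.prod(shape))
    p1 = np.clip(np.asarray(p_fg, dtype=float), 1e-6, None).ravel()
    p0 = np.clip(1.0 - np.asarray(p_fg, dtype=float), 1e-6, None).ravel()
    Y = np.array(list(itertools.product([0, 1], repeat=n)))
    E = np.where(Y == 1, -np.log(p1)[None], -np.log(p0)[None]).sum(axis=1)
    coords = np.array(list(np.ndindex(*shape)))
    img = np.asarray(image, dtype=float).ravel()
    r = params.window_radius
    # window-normalization constants of the two Gaussian kernels
    window = [np.array(o) for o in itertools.product(range(-r, r + 1), repeat=3)
              if any(o)]
    gs_norm = sum(np.exp(-float((o ** 2).sum()) / (2 * params.spatial_sigma ** 2))
                  for o in window)
    ga_norm = sum(np.exp(-float((o ** 2).sum()) / (2 * params.appearance_sigma_spatial ** 2))
                  for o in window)
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[j] - coords[i]
            if np.abs(d).max() > r:
                continue
            d2 = float((d ** 2).sum())
            w = (params.spatial_weight * np.exp(-d2 / (2 * params.spatial_sigma ** 2)) / gs_norm
                 + params.appearance_weight / ga_norm
                 * np.exp(-d2 / (2 * params.appearance_sigma_spatial ** 2)
                          - (img[i] - img[j]) ** 2 / (2 * params.intensity_sigma ** 2)))
            E += w * (Y[:, i] != Y[:, j])
    return E


class TestUncertaintyGate:
    def test_resets_above_threshold(self):
        p = np.full((3, 3, 1), 0.9)
        H = np.zeros((3, 3, 1))
        H[1, 1, 0] = 0.5
        gated = uncertainty_gate(p, H, theta=0.2)
        assert gated[1, 1, 1, 0] == 0.5 and gated[0, 1, 1, 0] == 0.5
        assert gated[1, 0, 0, 0] == pytest.approx(0.9)

    def test_below_and_exactly_at_threshold_unchanged(self):
        p = np.full((2, 1, 1), 0.8)
        for h in (0.1, 0.2):  # strict inequality: 0.2 itself is kept
            gated = uncertainty_gate(p, np.full((2, 1, 1), h), theta=0.2)
            np.testing.assert_allclose(gated[1], 0.8)

    def test_idempotent(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 4, 2))
        H = rng.uniform(0, 0.7, size=(4, 4, 2))
        once = uncertainty_gate(p, H, 0.2)
        twice = uncertainty_gate(once, H, 0.2)
        np.testing.assert_array_equal(once, twice)

    def test_shape_mismatch(self):
        with pytest.raises(FormatError):
            uncertainty_gate(np.full((2, 2, 2), 0.5), np.zeros((3, 3, 3)))


class TestCrfRefine:
    def test_zero_pairwise_weights_equal_unary_argmax(self, rng):
        p_fg = rng.uniform(0, 1, size=(6, 5, 4))
        image = rng.standard_normal((6, 5, 4))
        params = CrfParams(spatial_weight=0.0, appearance_weight=0.0)
        mask = crf_refine(p_fg, image, params).mask
        np.testing.assert_array_equal(mask, (p_fg >= 0.5).astype(np.uint8))

    def test_unanimous_probabilities_unchanged_on_uniform_image(self):
        p_fg = np.zeros((5, 5, 1))
        p_fg[1:4, 1:4, 0] = 1.0
        mask = crf_refine(p_fg, np.zeros((5, 5, 1)), CrfParams()).mask
        np.testing.assert_array_equal(mask, (p_fg > 0.5).astype(np.uint8))

    def test_isolated_weak_voxel_smoothed_away(self):
        """One p_fg=0.6 voxel inside confident background on a uniform image
        flips to background once the spatial weight dominates the margin."""
        p_fg = np.full((3, 3, 1), 0.05)
        p_fg[1, 1, 0] = 0.6
        params = CrfParams(spatial_weight=3.0, appearance_weight=0.0, iterations=10)
        mask = crf_refine(p_fg, np.zeros((3, 3, 1)), params).mask
        assert mask.sum() == 0
        # sanity: the smoothed labeling also has the lower true energy
        flipped = np.zeros((3, 3, 1), dtype=int)
        kept = flipped.copy()
        kept[1, 1, 0] = 1
        assert crf_energy(flipped, p_fg, np.zeros((3, 3, 1)), params) < \
            crf_energy(kept, p_fg, np.zeros((3, 3, 1)), params)

    @pytest.mark.parametrize("trial", range(8))
    def test_mean_field_energy_near_exhaustive_minimum(self, trial):
        """On 12-voxel instances the mean-field labeling's Gibbs energy is
        within 5% of the brute-force minimum over all 2^12 labelings."""
        rng = np.random.default_rng(1000 + trial)
        shape = (3, 2, 2)
        p_fg = rng.uniform(0.1, 0.9, size=shape)
        image = rng.standard_normal(shape)
        params = CrfParams(spatial_weight=float(rng.uniform(0, 2)),
                           appearance_weight=float(rng.uniform(0, 2)),
                           iterations=10)
        mask = crf_refine(p_fg, image, params).mask
        e_mf = crf_energy(mask, p_fg, image, params)
        energies = enumerate_gibbs_energies(p_fg, image, params)
        # the two energy routes agree on the returned labeling
        code = int("".join(str(v) for v in mask.ravel()), 2)
        assert e_mf == pytest.approx(energies[code], rel=1e-9)
        assert e_mf <= energies.min() * 1.05 + 1e-9


class TestUncertaintyAwareCrf:
    def test_infinite_threshold_matches_naive(self, rng):
        p_fg = rng.uniform(0, 1, size=(5, 5, 3))
        H = rng.uniform(0, 0.7, size=(5, 5, 3))
        image = rng.standard_normal((5, 5, 3))
        params = CrfParams(theta=np.inf)
        aware = uncertainty_aware_crf(p_fg, H, image, params).mask
        naive = crf_refine(p_fg, image, params).mask
        np.testing.assert_array_equal(aware, naive)

    def test_zero_entropy_matches_naive(self, rng):
        p_fg = rng.uniform(0, 1, size=(5, 5, 3))
        image = rng.standard_normal((5, 5, 3))
        params = CrfParams()
        aware = uncertainty_aware_crf(p_fg, np.zeros((5, 5, 3)), image, params).mask
        naive = crf_refine(p_fg, image, params).mask
        np.testing.assert_array_equal(aware, naive)

    def test_gate_lets_image_evidence_correct_missegmentation(self):
        """A confidently wrong, high-entropy region inside a bright object:
        the gated CRF recovers at least as much of it as the naive CRF."""
        shape = (9, 9, 3)
        image = np.zeros(shape)
        image[2:7, 2:7, :] = 2.0  # bright object
        truth = (image > 1).astype(np.uint8)
        p_fg = np.where(truth > 0, 0.9, 0.1)
        p_fg[4:7, 4:7, :] = 0.15  # mis-segmented corner, confidently wrong
        H = np.zeros(shape)
        H[4:7, 4:7, :] = 0.6  # ... but the TTA members disagreed there
        params = CrfParams(spatial_weight=0.5, appearance_weight=3.0,
                           intensity_sigma=0.5, iterations=10)
        naive = crf_refine(p_fg, image, params, task="whole").mask
        aware = uncertainty_aware_crf(p_fg, H, image, params, task="whole").mask
        wrong_region = np.zeros(shape, dtype=bool)
        wrong_region[4:7, 4:7, :] = True
        recovered_naive = int((naive[wrong_region] == 1).sum())
        recovered_aware = int((aware[wrong_region] == 1).sum())
        assert recovered_aware >= recovered_naive
        assert recovered_aware == wrong_region.sum()  # fully corrected


def test_invalid_params_rejected():
    with pytest.raises(FormatError):
        CrfParams(spatial_weight=-1.0)
    with pytest.raises(FormatError):
        CrfParams(iterations=0)
    with pytest.raises(FormatError):
        CrfParams(theta=-0.1)
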