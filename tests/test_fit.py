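"""Kabsch superposition: exact recovery, chirality handling, robustness."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import shelxfrag as sf
from shelxfrag.errors import (CollinearPointsError,
                              CorrespondenceMismatchError, TooFewPointsError)


def random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-10, 10, size=3)
    return rot, trans


def test_identity_and_pure_translation():
    pts = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0.3, 0.4, 1.1]])
    tf, rmsd = sf.kabsch_fit(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
    tf, rmsd = sf.kabsch_fit(pts, pts + [1, 2, 3])
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(tf.translation, [1, 2, 3])


def test_random_transform_recovery():
    rng = np.random.default_rng(11)
    for _ in range(20):
        pts = rng.uniform(-5, 5, size=(5, 3))
        rot, trans = random_rigid(rng)
        tf, rmsd = sf.kabsch_fit(pts, pts @ rot.T + trans)
        assert rmsd < 1e-9
        assert np.allclose(tf.rotation, rot, atol=1e-9)


def test_rotation_is_always_proper():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = rng.uniform(-3, 3, size=(4, 3))
        b = rng.uniform(-3, 3, size=(4, 3))
        tf, _ = sf.kabsch_fit(a, b)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(tf.rotation.T @ tf.rotation, np.eye(3), atol=1e-9)


def test_mirror_image_of_chiral_set_needs_inversion(db):
    # a chiral 4-point set: mirror it; a proper rotation cannot superpose it
    pts = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 1.9]])
    mirror = pts * [1, 1, -1]
    _tf, rmsd = sf.kabsch_fit(pts, mirror)
    assert rmsd > 0.1
    inverted = 2 * pts.mean(axis=0) - pts   # inversion, then proper fit
    _tf, rmsd_inv = sf.kabsch_fit(inverted, mirror)
    assert rmsd_inv < 1e-9


def test_rmsd_invariant_under_common_rigid_motion():
    rng = np.random.default_rng(5)
    a = rng.uniform(-4, 4, size=(6, 3))
    b = a + rng.normal(0, 0.3, size=a.shape)
    _, rmsd0 = sf.kabsch_fit(a, b)
    rot, trans = random_rigid(rng)
    _, rmsd1 = sf.kabsch_fit(a @ rot.T + trans, b @ rot.T + trans)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


def test_squared_residual_never_increases_when_dropping_a_point():
    # the least-squares objective (sum of squared residuals) is monotone
    # under point removal; per-point rmsd is not, since n shrinks too
    rng = np.random.default_rng(9)
    a = rng.uniform(-4, 4, size=(6, 3))
    b = a + rng.normal(0, 0.2, size=a.shape)
    _, full = sf.kabsch_fit(a, b)
    for k in range(6):
        keep = [i for i in range(6) if i != k]
        _, part = sf.kabsch_fit(a[keep], b[keep])
        assert len(keep) * part ** 2 <= 6 * full ** 2 + 1e-12


@pytest.mark.parametrize("bad_call", [
    lambda: sf.kabsch_fit(np.zeros((3, 3)), np.zeros((4, 3))),
    lambda: sf.kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3))),
    lambda: sf.kabsch_fit([[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                          [[0, 0, 0], [0, 1, 0], [0, 0, 1]]),
])
def test_degenerate_inputs_rejected(bad_call):
    with pytest.raises((CorrespondenceMismatchError, TooFewPointsError,
                        CollinearPointsError)):
        bad_call()


def test_fit_fragment_identity_and_known_motion(ccf3, db):
    cart = sf.frac_to_cart(ccf3.coords_array(), ccf3.cell)
    fit = sf.fit_fragment(ccf3, ccf3.atom_names(), cart)
    assert fit.rmsd < 1e-12
    assert np.allclose(fit.positions, cart, atol=1e-12)
    # fit on a 5-atom subset of a known motion must carry all 14 atoms along
    rng = np.random.default_rng(21)
    rot, trans = random_rigid(rng)
    moved = cart @ rot.T + trans
    names = ["O1", "C1", "C2", "C3", "C4"]
    rows = [ccf3.atom_names().index(n) for n in names]
    fit = sf.fit_fragment(ccf3, names, moved[rows])
    assert fit.rmsd < 1e-9
    assert np.max(np.abs(fit.positions - moved)) < 1e-9


def test_fit_fragment_unknown_source_name(ccf3):
    with pytest.raises(CorrespondenceMismatchError):
        sf.fit_fragment(ccf3, ["O1", "C1", "XX"], np.zeros((3, 3)))


def test_inversion_immaterial_for_planar_fragment(db):
    tol = sf.lookup(db, "toluene")
    cart = sf.frac_to_cart(tol.coords_array(), tol.cell)
    names = ["C1", "C2", "C4"]
    rows = [tol.atom_names().index(n) for n in names]
    plain = sf.fit_fragment(tol, names, cart[rows], invert=False)
    inv = sf.fit_fragment(tol, names, cart[rows], invert=True)
    assert inv.rmsd == pytest.approx(plain.rmsd, abs=1e-9)


def test_inversion_required_for_chiral_thf(db):
    thf = sf.lookup(db, "THF")
    cart = sf.frac_to_cart(thf.coords_array(), thf.cell)
    enantiomer = cart * [1, 1, -1]
    names = list(thf.atom_names())
    plain = sf.fit_fragment(thf, names, enantiomer, invert=False)
    inv = sf.fit_fragment(thf, names, enantiomer, invert=True)
    assert plain.rmsd > 0.05
    assert inv.rmsd < 1e-9


def test_noisy_rotation_recovery_rate():
    """With 0.1 A Gaussian noise on 5 anchors the recovered rotation is
    within 5 degrees in at least 95% of seeded trials."""
    rng = np.random.default_rng(2024)
    good = 0
    n_trials = 200
    for _ in range(n_trials):
        pts = rng.uniform(-3, 3, size=(5, 3))
        rot, trans = random_rigid(rng)
        noisy = pts @ rot.T + trans + rng.normal(0, 0.1, size=pts.shape)
        tf, _ = sf.kabsch_fit(pts, noisy)
        err = Rotation.from_matrix(tf.rotation @ rot.T).magnitude()
        if np.degrees(err) < 5.0:
            good += 1
    assert good >= 0.95 * n_trials
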