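import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cobbcurve as cc
from cobbcurve import detect

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# the classical detector logs a warning per rejected component; keep the
# test output readable
logging.getLogger("cobbcurve.detect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def straight_spec():
    return cc.PhantomSpec(curve_coefficients=[450.0], n_vertebrae=12, seed=0)


@pytest.fixture(scope="session")
def c33_spec():
    """Single C-curve with a ground-truth Cobb angle of exactly 33 deg."""
    return cc.spec_from_angles(1, angle_up=33.0, n_vertebrae=12, seed=0)


@pytest.fixture(scope="session")
def s_curve_spec():
    """Double curve: 30 deg superior, 20 deg inferior, one inflection."""
    return cc.spec_from_angles(2, angle_up=30.0, angle_low=20.0, n_vertebrae=14, seed=0)


@pytest.fixture(scope="session")
def s_curve_layout(s_curve_spec):
    boxes, truth = cc.layout_phantom(s_curve_spec)
    seq = detect.VertebraSequence(
        boxes=boxes, image_size=s_curve_spec.image_size, source="annotation"
    )
    return seq, truth


@pytest.fixture(scope="session")
def rendered_c33(c33_spec):
    """Noise-free rendered image of the 33-deg phantom."""
    image, boxes, truth = cc.generate_phantom(c33_spec)
    return image, boxes, truth


def sequence_from_boxes(boxes, image_size=(900, 1900)):
    return detect.VertebraSequence(boxes=list(boxes), image_size=image_size)
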