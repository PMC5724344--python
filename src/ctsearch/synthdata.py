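"""Synthetic head-CT phantom studies with known lesion-class ground truth.

Real hospital corpora cannot ship with a retrieval engine, so this module
generates reproducible stand-ins: each study is a stack of 2-D phantom
slices — an elliptical skull ring (bone HU) around a brain interior (soft
tissue HU) — carrying one of four lesion classes:

* ``haemorrhage``   — hyperdense elliptical blob (fresh blood, ~80 HU)
* ``infarct``       — hypodense wedge (ischaemic territory, ~10 HU)
* ``calcification`` — small very bright dots (~400 HU)
* ``normal``        — no lesion

Lesion geometry is jittered per seed within the brain so retrieval cannot
latch onto a single fixed shape. Reports are drawn from class-matched
templates that include an anamnesis question ("Suspected <finding>?") and a
findings sentence, asserted or negated, so negation filtering and the
anamnesis/report field-scope distinction are both exercisable: a *normal*
study's report explicitly negates the finding its anamnesis asks about.

Everything is deterministic given the spec (including its seed); the HU
palette mimics real head-CT contrast ordering but no anatomical realism is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import SEXES, Study, write_study_files, write_truth_table  # noqa: F401
from .textproc import ReportDocument

__all__ = [
    "LESION_CLASSES",
    "HU",
    "PhantomSpec",
    "LesionGeometry",
    "generate_study",
    "generate_corpus",
    "largest_remainder_counts",
]

LESION_CLASSES = ("haemorrhage", "infarct", "calcification", "normal")

#: HU palette (fixture constants): chosen to mimic head-CT contrast ordering.
HU = {
    "background": -1000.0,
    "skull": 1000.0,
    "brain": 40.0,
    "haemorrhage": 80.0,
    "infarct": 10.0,
    "calcification": 400.0,
}

_FINDING_TERM = {
    "haemorrhage": "haemorrhage",
    "infarct": "infarct",
    "calcification": "calcification",
}

# >=3 positive templates per class
_POSITIVE_TEMPLATES = {
    "haemorrhage": [
        "Acute haemorrhage in the right frontal lobe.",
        "Small subdural haemorrhage along the left convexity.",
        "Intraparenchymal haemorrhage with mild surrounding oedema.",
    ],
    "infarct": [
        "Recent infarct in the left middle cerebral artery territory.",
        "Established infarct in the right occipital lobe.",
        "Subacute infarct with low attenuation in the basal ganglia.",
    ],
    "calcification": [
        "Coarse calcification of the choroid plexus.",
        "Scattered calcification in the basal ganglia.",
        "Dural calcification adjacent to the vertex.",
    ],
}

# >=2 negated templates per class
_NEGATED_TEMPLATES = {
    "haemorrhage": [
        "No haemorrhage seen.",
        "No acute haemorrhage or mass effect.",
    ],
    "infarct": [
        "No infarct seen.",
        "No recent infarct identified.",
    ],
    "calcification": [
        "No abnormal calcification seen.",
        "No pathological calcification identified.",
    ],
}

_ANAMNESIS_TEMPLATES = [
    "Suspected {finding}?",
    "Head trauma, {finding} to be excluded?",
    "Any signs of {finding}?",
]

_NORMAL_CLOSING = "Normal intracranial appearances."


@dataclass(frozen=True)
class LesionGeometry:
    """Ellipse in pixel coordinates bounding the lesion."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (row, col)
    angle_deg: float = 0.0  # wedge orientation for infarcts

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Half-open (r0, r1, c0, c1) bounding rectangle."""
        (cr, cc), (ar, ac) = self.center, self.axes
        return (
            int(np.floor(cr - ar)),
            int(np.ceil(cr + ar)) + 1,
            int(np.floor(cc - ac)),
            int(np.ceil(cc + ac)) + 1,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one synthetic study; identical specs yield identical output."""

    seed: int
    lesion_class: str = "normal"
    image_size: int = 128
    n_slices: int = 12
    lesion_geometry: LesionGeometry | None = None  # None → jittered from seed
    noise_sd: float = 3.0  # additive Gaussian intensity noise, HU
    patient_age: int = 60
    patient_sex: str = "M"
    study_code: str = "HCT"
    study_id: str | None = None  # None → derived from seed

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(
                f"lesion_class must be one of {LESION_CLASSES}, "
                f"got {self.lesion_class!r}"
            )
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.patient_sex not in SEXES:
            raise ValueError(f"patient_sex must be one of {SEXES}")
        if self.lesion_geometry is not None and self.lesion_class != "normal":
            _check_inside_brain(self.lesion_geometry, self.image_size)


def _brain_axes(size: int) -> tuple[float, float]:
    return 0.36 * size, 0.30 * size


def _skull_axes(size: int) -> tuple[float, float]:
    return 0.44 * size, 0.38 * size


def _check_inside_brain(geom: LesionGeometry, size: int) -> None:
    a_br, b_br = _brain_axes(size)
    center = (size - 1) / 2.0
    (cr, cc), (ar, ac) = geom.center, geom.axes
    if ar >= a_br or ac >= b_br:
        raise ValueError("lesion axes exceed brain ellipse")
    # conservative containment: shrink the brain ellipse by the lesion axes
    u = (cr - center) / (a_br - ar)
    v = (cc - center) / (b_br - ac)
    if u * u + v * v > 1.0:
        raise ValueError("lesion_geometry not fully inside the brain ellipse")


def _sample_geometry(rng: np.random.Generator, spec: PhantomSpec) -> LesionGeometry:
    size = spec.image_size
    a_br, b_br = _brain_axes(size)
    center = (size - 1) / 2.0
    if spec.lesion_class == "calcification":
        axes = (
            rng.uniform(0.05, 0.09) * size,
            rng.uniform(0.05, 0.09) * size,
        )
    else:
        axes = (
            rng.uniform(0.08, 0.14) * size,
            rng.uniform(0.08, 0.14) * size,
        )
    # rejection-free placement inside the shrunken brain ellipse
    theta = rng.uniform(0, 2 * np.pi)
    rho = np.sqrt(rng.uniform(0, 1)) * 0.9
    cr = center + rho * (a_br - axes[0]) * np.sin(theta)
    cc = center + rho * (b_br - axes[1]) * np.cos(theta)
    return LesionGeometry(
        center=(float(cr), float(cc)),
        axes=(float(axes[0]), float(axes[1])),
        angle_deg=float(rng.uniform(0, 360)),
    )


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _render_base(size: int) -> np.ndarray:
    img = np.full((size, size), HU["background"], dtype=np.float64)
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    img[_ellipse_mask((size, size), center, _skull_axes(size))] = HU["skull"]
    img[_ellipse_mask((size, size), center, _brain_axes(size))] = HU["brain"]
    return img


def _render_lesion(
    img: np.ndarray, cls: str, geom: LesionGeometry, rng: np.random.Generator
) -> None:
    shape = img.shape
    ellipse = _ellipse_mask(shape, geom.center, geom.axes)
    if cls == "haemorrhage":
        img[ellipse] = HU["haemorrhage"]
    elif cls == "infarct":
        # hypodense wedge: the sector of the lesion ellipse spanning 120 deg
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        ang = np.degrees(
            np.arctan2(rr - geom.center[0], cc - geom.center[1])
        )  # [-180, 180]
        rel = (ang - geom.angle_deg) % 360.0
        img[ellipse & (rel <= 120.0)] = HU["infarct"]
    elif cls == "calcification":
        for _ in range(5):
            t = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1))
            dr = geom.center[0] + rho * (geom.axes[0] - 2.0) * np.sin(t)
            dc = geom.center[1] + rho * (geom.axes[1] - 2.0) * np.cos(t)
            dot = _ellipse_mask(shape, (dr, dc), (2.0, 2.0))
            img[dot] = HU["calcification"]


def _make_report(
    study_id: str, cls: str, rng: np.random.Generator
) -> ReportDocument:
    if cls == "normal":
        # the anamnesis asks about a finding; the report negates it
        asked = _FINDING_TERM[
            list(_FINDING_TERM)[int(rng.integers(len(_FINDING_TERM)))]
        ]
        anamnesis = _ANAMNESIS_TEMPLATES[
            int(rng.integers(len(_ANAMNESIS_TEMPLATES)))
        ].format(finding=asked)
        negated = _NEGATED_TEMPLATES[asked][
            int(rng.integers(len(_NEGATED_TEMPLATES[asked])))
        ]
        report_text = f"{negated} {_NORMAL_CLOSING}"
    else:
        finding = _FINDING_TERM[cls]
        anamnesis = _ANAMNESIS_TEMPLATES[
            int(rng.integers(len(_ANAMNESIS_TEMPLATES)))
        ].format(finding=finding)
        positive = _POSITIVE_TEMPLATES[cls][
            int(rng.integers(len(_POSITIVE_TEMPLATES[cls])))
        ]
        # negate a different finding in the same report to exercise filtering
        others = [t for c, t in _FINDING_TERM.items() if c != cls]
        other = others[int(rng.integers(len(others)))]
        negated = _NEGATED_TEMPLATES[other][
            int(rng.integers(len(_NEGATED_TEMPLATES[other])))
        ]
        report_text = f"{positive} {negated}"
    return ReportDocument(
        study_id=study_id, anamnesis=anamnesis, report_text=report_text
    )


def generate_study(spec: PhantomSpec) -> Study:
    """Render one synthetic study from its spec. Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    study_id = spec.study_id or f"S{spec.seed:08d}"

    geom = spec.lesion_geometry
    if geom is None and spec.lesion_class != "normal":
        geom = _sample_geometry(rng, spec)
    if geom is not None and spec.lesion_class != "normal":
        _check_inside_brain(geom, spec.image_size)

    base = _render_base(spec.image_size)
    if spec.lesion_class != "normal":
        _render_lesion(base, spec.lesion_class, geom, rng)

    slices = []
    for _ in range(spec.n_slices):
        sl = base.copy()
        if spec.noise_sd > 0:
            sl += rng.normal(0.0, spec.noise_sd, size=sl.shape)
        slices.append(np.rint(sl))  # CT HU values are integral

    report = _make_report(study_id, spec.lesion_class, rng)
    study = Study(
        study_id=study_id,
        slices=slices,
        report=report,
        patient_age=spec.patient_age,
        patient_sex=spec.patient_sex,
        study_code=spec.study_code,
        truth_class=spec.lesion_class,
    )
    # stash the geometry so callers (e.g. ROI queries) can target the lesion
    study.lesion_geometry = geom  # type: ignore[attr-defined]
    return study


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer class counts summing to n via largest-remainder rounding.

    Ties in fractional remainder resolve in mapping insertion order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total}")
    exact = {c: n * p for c, p in proportions.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    shortfall = n - sum(counts.values())
    order = sorted(
        proportions, key=lambda c: exact[c] - counts[c], reverse=True
    )  # stable: insertion order breaks remainder ties
    for c in order[:shortfall]:
        counts[c] += 1
    return counts


DEFAULT_CLASS_MIX = {c: 0.25 for c in LESION_CLASSES}


def generate_corpus(
    n: int,
    class_mix: dict[str, float] | None = None,
    base_seed: int = 0,
    image_size: int = 128,
    n_slices: int = 12,
    noise_sd: float = 3.0,
) -> tuple[list[Study], dict[str, str]]:
    """Generate `n` studies with class counts by largest-remainder rounding.

    Per-study seeds, ages, sexes and the class assignment order all derive
    deterministically from `base_seed`. Returns the studies plus the
    study_id → truth class table.
    """
    class_mix = class_mix or DEFAULT_CLASS_MIX
    for cls in class_mix:
        if cls not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {cls!r}")
    counts = largest_remainder_counts(n, class_mix)
    labels = [c for c, k in counts.items() for _ in range(k)]
    rng = np.random.default_rng(base_seed)
    labels = [labels[i] for i in rng.permutation(n)]
    seeds = rng.integers(0, 2**31 - 1, size=n)
    ages = rng.integers(18, 95, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    studies: list[Study] = []
    truth: dict[str, str] = {}
    for i in range(n):
        sid = f"S{i:04d}"
        spec = PhantomSpec(
            seed=int(seeds[i]),
            lesion_class=labels[i],
            image_size=image_size,
            n_slices=n_slices,
            noise_sd=noise_sd,
            patient_age=int(ages[i]),
            patient_sex=str(sexes[i]),
            study_id=sid,
        )
        studies.append(generate_study(spec))
        truth[sid] = labels[i]
    return studies, truth
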