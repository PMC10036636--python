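"""Labelled MUAP-window generation for training decomposition networks.

Each training example is a multichannel window built from a bank of
simulated MUAP templates: with the configured activity probability the
target MU's template is placed at the window centre (positive label),
otherwise the centre stays empty (negative label); a random number of
templates from *other* MU classes is superimposed at uniform random
offsets, and standard-normal noise is added.  The label refers to
target-class activity within the central label span.

Defaults follow the standard recipe for pre-training decomposition
networks: 160-sample windows at 2048 Hz with 130 channels, 50% activity
probability, up to 4 distractor templates, unit noise, and an 80-sample
central label span; datasets are organised as independent sets (e.g. 64
sets of 5 MUAP classes), each set with its own label space.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "build_window",
    "build_dataset",
    "save_dataset",
    "label_for_offset",
]


@dataclass(frozen=True)
class WindowSpec:
    width: int = 160
    n_channels: int = 130
    fs: float = 2048.0
    activity_probability: float = 0.5
    max_superpositions: int = 4
    noise_std: float = 1.0
    label_span: int = 80
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if not 0 <= self.activity_probability <= 1:
            raise ValueError("activity probability must be in [0, 1]")
        if self.label_span > self.width:
            raise ValueError("label span cannot exceed window width")


def _place(window: np.ndarray, template: np.ndarray, start: int) -> None:
    width = window.shape[1]
    lw = template.shape[1]
    lo = max(start, 0)
    hi = min(start + lw, width)
    if hi > lo:
        window[:, lo:hi] += template[:, lo - start : hi - start]


def label_for_offset(spec: WindowSpec, offset: int) -> int:
    """Centre-label rule: a target discharge placed ``offset`` samples
    off-centre is positive iff it stays within half the label span."""
    return int(abs(int(offset)) <= spec.label_span // 2)


def build_window(
    templates: list,
    target_class: int | None,
    spec: WindowSpec,
    rng: np.random.Generator | None = None,
    target_offset: int = 0,
) -> tuple:
    """Build one (window, label) pair.

    ``templates``: list of (n_channels, n_t) arrays, one per MU class of
    the set.  ``target_class`` selects the class whose activity is
    labelled (None draws one uniformly); ``target_offset`` shifts the
    target template off-centre (the label follows
    :func:`label_for_offset`).  Returns (window, label) with window of
    shape (n_channels, width) and a binary label.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    for t in templates:
        if t.shape[0] != spec.n_channels:
            raise ValueError("template channel count differs from the window spec")
        if t.shape[1] > spec.width:
            raise ValueError(
                f"template of {t.shape[1]} samples is wider than the "
                f"{spec.width}-sample window"
            )
    if target_class is None:
        target_class = int(rng.integers(len(templates)))
    window = np.zeros((spec.n_channels, spec.width))
    active = bool(rng.uniform() < spec.activity_probability)
    label = 0
    if active:
        tpl = templates[target_class]
        start = (spec.width - tpl.shape[1]) // 2 + int(target_offset)
        _place(window, tpl, start)
        label = label_for_offset(spec, target_offset)
    others = [c for c in range(len(templates)) if c != target_class]
    if others and spec.max_superpositions > 0:
        n_extra = int(rng.integers(0, spec.max_superpositions + 1))
        for _ in range(n_extra):
            c = int(rng.choice(others))
            tpl = templates[c]
            # keep at least one sample of the distractor inside the window
            start = int(rng.integers(1 - tpl.shape[1], spec.width - 1))
            _place(window, tpl, start)
    if spec.noise_std > 0:
        window = window + rng.normal(0.0, spec.noise_std, window.shape)
    return window, label


def build_dataset(template_sets: list, windows_per_set: int, spec: WindowSpec) -> dict:
    """Build labelled windows per MUAP set.

    ``template_sets``: list of sets, each a list of per-class templates
    (e.g. 64 sets of 5).  Each set has its own label space (the target
    class cycles uniformly).  Returns a manifest dict with ``windows``
    (float32 [n, channels, width]), ``labels``, ``set_id``,
    ``target_class`` arrays and the generating spec.
    """
    if not template_sets or any(len(s) == 0 for s in template_sets):
        raise ValueError("every template set must be non-empty")
    rng = np.random.default_rng(spec.rng_seed)
    windows, labels, set_ids, targets = [], [], [], []
    for si, templates in enumerate(template_sets):
        for w in range(windows_per_set):
            cls = w % len(templates)
            win, lab = build_window(templates, cls, spec, rng)
            windows.append(win.astype(np.float32))
            labels.append(lab)
            set_ids.append(si)
            targets.append(cls)
    shape = (len(windows), spec.n_channels, spec.width)
    return {
        "windows": np.asarray(windows, dtype=np.float32).reshape(shape)
        if windows
        else np.zeros(shape, dtype=np.float32),
        "labels": np.asarray(labels, dtype=np.int8),
        "set_id": np.asarray(set_ids, dtype=np.int32),
        "target_class": np.asarray(targets, dtype=np.int32),
        "manifest": {
            "spec": asdict(spec),
            "n_sets": len(template_sets),
            "classes_per_set": [len(s) for s in template_sets],
            "windows_per_set": windows_per_set,
        },
    }


def save_dataset(dataset: dict, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for key in ("windows", "labels", "set_id", "target_class"):
            f.create_dataset(key, data=dataset[key])
        f.attrs["manifest"] = json.dumps(dataset["manifest"])
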