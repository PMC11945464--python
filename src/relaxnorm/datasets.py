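"""Bundled example data.

``load_example_welders`` returns the exposure table of ten welders (five
high-exposure, five low-exposure) from a published occupational Mn-exposure
cohort; ages, mean airborne Mn and the CEI_3M / CEI_Life cumulative exposure
indices are as reported. It is the standard worked example for
:func:`relaxnorm.exposure.classify_exposure`.
"""

from __future__ import annotations

from importlib import resources

from .volume_io import SubjectRecord, read_cohort_table

__all__ = ["load_example_welders"]


def load_example_welders() -> list[SubjectRecord]:
    """Ten welder records (W01-W10) with CEI exposure indices."""
    path = resources.files("relaxnorm.data") / "welders_exposure.csv"
    with resources.as_file(path) as p:
        return read_cohort_table(p)
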