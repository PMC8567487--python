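"""Bundled normative reference tables and example case measurements.

``histo_reference`` and ``bmdd_reference`` hold the normative (mean, SD)
rows used for Z-scoring; ``example_histomorphometry`` / ``example_bmdd``
hold published measurements for two adult male cases of early-onset
osteoporosis, shipped so the Z-score and compartment-comparison calculus can
be exercised without images.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .zscore import ReferenceStat


def _read(name: str) -> pd.DataFrame:
    with resources.files("bonematrix.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_histo_reference(path=None) -> pd.DataFrame:
    """Normative histomorphometry table: parameter, sex, age_lo, age_hi, mean, sd."""
    return pd.read_csv(path) if path is not None else _read("histo_reference.csv")


def load_bmdd_reference(path=None) -> dict[str, ReferenceStat]:
    """Adult trabecular BMDD reference as {parameter: ReferenceStat}."""
    df = pd.read_csv(path) if path is not None else _read("bmdd_reference.csv")
    return {
        row.parameter: ReferenceStat(
            parameter=row.parameter,
            mean=float(row.loc["mean"]),
            sd=float(row.sd),
            source=str(row.get("source", "")),
        )
        for _, row in df.iterrows()
    }


def load_example_histomorphometry() -> pd.DataFrame:
    """Measured histomorphometric parameters for the two bundled cases (long format)."""
    return _read("example_histomorphometry.csv")


def load_example_bmdd() -> pd.DataFrame:
    """Measured BMDD parameters per compartment for the two bundled cases."""
    return _read("example_bmdd.csv")


def example_histo_values(case: str) -> dict[str, float]:
    """Parameter -> value dict for one bundled case ('case1' or 'case2')."""
    df = load_example_histomorphometry()
    sub = df[df.case == case]
    if sub.empty:
        raise KeyError(f"unknown case {case!r}; available: {sorted(df.case.unique())}")
    return dict(zip(sub.parameter, sub.value.astype(float)))


def example_bmdd_values(case: str, compartment: str) -> dict[str, float]:
    """Parameter -> value dict for one bundled case and compartment."""
    df = load_example_bmdd()
    sub = df[(df.case == case) & (df.compartment == compartment)]
    if sub.empty:
        raise KeyError(f"no rows for case={case!r}, compartment={compartment!r}")
    return dict(zip(sub.parameter, sub.value.astype(float)))
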