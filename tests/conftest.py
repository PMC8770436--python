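"""Shared fixtures: coarse meshes and session-scoped solved cases.

The solved-case fixtures deliberately use meshes far coarser than a
production run so the whole suite stays within a few minutes; quantities
asserted on them are either exact properties (linearity, locations,
orderings) or compared at correspondingly loose tolerances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from micromotion_fem import MeshParams, MicromotionModel

# ~7.5k elements: small enough for the deterministic direct solver.
COARSE = MeshParams(n_through_thickness=3, near_size=20.0, grading=1.6,
                    far_size=220.0)
# ~25k elements: the shared mesh for material comparisons.
SHARED = MeshParams(n_through_thickness=4, near_size=11.0, grading=1.45,
                    far_size=140.0)


def fit_case(case, *, mesh, displacement=None, method=None, **overrides):
    m = MicromotionModel.from_case(case, mesh=mesh, **(
        {"displacement": displacement, **overrides} if displacement else overrides))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.fit(method=method)


@pytest.fixture(scope="session")
def stiff_direct_solves():
    """Silicon probe solved independently at 1, 10 and 20 um with the
    deterministic direct solver on one fixed coarse mesh."""
    return {d: fit_case(1, mesh=COARSE, displacement=float(d),
                        method="direct") for d in (1, 10, 20)}


@pytest.fixture(scope="session")
def material_solves():
    """One solve per probe material at 1 um on the shared 25 um-thick mesh."""
    return {
        "silicon": fit_case(1, mesh=SHARED),
        "polyimide": fit_case(4, mesh=SHARED),
        "hypothetical": fit_case(5, mesh=SHARED),
        "pvac_nc": fit_case(7, mesh=SHARED),
    }


@pytest.fixture(scope="session")
def compliant63_solve():
    """The 63 um-thick compliant probe at 1 um on the shared mesh params."""
    return fit_case(6, mesh=SHARED)
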