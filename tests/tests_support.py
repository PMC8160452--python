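"""Shared helpers for the test suite."""

import numpy as np

from metaga.design import DesignMatrix


def design_from_array(X, names=None):
    """Wrap a plain numeric matrix as a DesignMatrix with an intercept."""
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]
    cols = ["intercept"] + list(names)
    prov = {c: ((c,), "main") for c in cols}
    prov["intercept"] = ((), "intercept")
    return DesignMatrix(column_names=cols,
                        values=np.column_stack([np.ones(n), X]),
                        provenance=prov)
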