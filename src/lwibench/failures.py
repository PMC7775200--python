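"""Typed method-failure signal.

A missing-data handler or a downstream model fit can be *infeasible* for a
given incomplete data set (e.g., listwise deletion leaving too few complete
observations).  That outcome is part of the benchmark's result space, not a
bug: the pipeline catches :class:`MethodFailure`, records it, and the
grand-mean bias for that (proportion, method) cell becomes undefined.
"""

from __future__ import annotations


class MethodFailure(Exception):
    """A handling method or model fit could not produce a result.

    Parameters
    ----------
    method : str
        Identifier of the failing step (e.g. ``"listwise"``, ``"panel_re"``).
    reason : str
        Human-readable diagnosis (e.g. ``"0 complete rows"``).
    """

    def __init__(self, method: str, reason: str):
        self.method = method
        self.reason = reason
        super().__init__(f"{method}: {reason}")
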