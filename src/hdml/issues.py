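"""Graded validation issues.

Issues are data, not exceptions: well-formedness checks and the validator
return lists of :class:`ValidationIssue` so callers can grade, filter and
render them.  ``severity`` is one of ``error`` (the tree violates its
schema), ``warning`` (suspicious but readable) and ``best_practice``
(recommended metadata missing).
"""

from __future__ import annotations

from dataclasses import dataclass

SEVERITIES = ("error", "warning", "best_practice")
_SEVERITY_RANK = {s: i for i, s in enumerate(SEVERITIES)}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str
    path: str
    rule_id: str
    message: str

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")

    def sort_key(self):
        """Stable report order: errors first, then by path, then rule."""
        return (_SEVERITY_RANK[self.severity], self.path, self.rule_id)


def errors_only(issues):
    return [i for i in issues if i.severity == "error"]
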