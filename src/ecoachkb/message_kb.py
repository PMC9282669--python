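"""Registry of recommendation messages.

Seventeen messages are defined: A-1 … A-16 (activity recommendations) and
C-1 (the contextual weather recommendation).  Each carries an intent (ToDo —
a concrete instruction for the next day — or Informal — status and
encouragement), the four message components (time, element, action,
subject), an optional exclusivity group, and a text template.  The codes and
intents are the stable contract; the template texts are synthetic
placeholders meant to be localized by deployments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

__all__ = ["MessageSpec", "RenderError", "registry", "lookup", "render"]

ONCE_A_DAY_GROUP = frozenset({"A-13", "A-14"})
WEEKLY_DETERMINANTS = ("A-15", "A-16")


class RenderError(KeyError):
    """A template placeholder had no binding; names the missing slot."""


@dataclass(frozen=True)
class MessageSpec:
    code: str
    intent: str  # "ToDo" | "Informal"
    components: dict
    exclusivity_group: str | None
    text_template: str

    def __post_init__(self) -> None:
        if self.intent not in ("ToDo", "Informal"):
            raise ValueError(f"{self.code}: intent must be ToDo or Informal")
        missing = {"time", "element", "action", "subject"} - set(self.components)
        if missing:
            raise ValueError(f"{self.code}: missing components {sorted(missing)}")


@lru_cache(maxsize=1)
def _load() -> tuple[MessageSpec, ...]:
    raw = json.loads(
        (files("ecoachkb") / "messages" / "messages.json").read_text(encoding="utf-8")
    )
    specs = tuple(
        MessageSpec(
            code=m["code"],
            intent=m["intent"],
            components=m["components"],
            exclusivity_group=m.get("exclusivity_group"),
            text_template=m["text_template"],
        )
        for m in raw["messages"]
    )
    codes = [s.code for s in specs]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate message codes in registry")
    for code in ONCE_A_DAY_GROUP:
        spec = next(s for s in specs if s.code == code)
        if spec.intent != "Informal" or spec.exclusivity_group != "once_a_day":
            raise ValueError(f"{code} must be Informal and in the once_a_day group")
    return specs


def registry() -> list[MessageSpec]:
    """All message specifications (A-1 … A-16 and C-1)."""
    return list(_load())


def lookup(code: str) -> MessageSpec:
    for spec in _load():
        if spec.code == code:
            return spec
    raise KeyError(f"unknown message code {code!r}")


_PLACEHOLDER = re.compile(r"\{([a-zA-Z_][a-zA-Z0-9_]*)\}")


def render(spec: MessageSpec, context: dict) -> str:
    """Deterministic template substitution; unknown extra bindings are ignored."""
    def _sub(match: re.Match) -> str:
        name = match.group(1)
        if name not in context:
            raise RenderError(name)
        return str(context[name])

    return _PLACEHOLDER.sub(_sub, spec.text_template)
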