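"""Canonical rendering of treatment regimens and treatment transitions."""

from __future__ import annotations

NO_TREATMENT = "no treatment"
NO_CHANGE = "no change"
NO_CHANGE_OPTION = "No change"


def render_label(components) -> str:
    """Render a regimen as its components sorted lexicographically, '_'-joined.

    An empty component set renders as the sentinel ``"no treatment"``.
    """
    comps = sorted(set(components))
    return "_".join(comps) if comps else NO_TREATMENT


def transition_label(new: str, active: str) -> str:
    """Render a treatment decision, e.g. ``Metformin_new+no treatment_stop``.

    A decision whose new regimen equals the active one is the baseline
    option ``"No change"``.
    """
    if new == NO_CHANGE or new == active:
        return NO_CHANGE_OPTION
    raw = f"{new}_new+{active}_stop"
    return raw[0].upper() + raw[1:]


def new_regimen_of(option: str) -> str:
    """The new-regimen part of a rendered transition label (lower-cased)."""
    if option == NO_CHANGE_OPTION:
        return NO_CHANGE
    head = option.split("_new+", 1)[0]
    return head[0].lower() + head[1:]
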