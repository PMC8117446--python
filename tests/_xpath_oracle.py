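"""Brute-force tree-walk oracle for the registry's XPath subset.

Independent of the implementation under test: parses with
xml.etree.ElementTree (not lxml) and evaluates path expressions by
exhaustive recursive descent.  Supports exactly the expression shapes the
manuscript template uses:

* ``//A/B/C`` — descendant-or-self start, then child steps
* ``A/B`` — child steps relative to the document root
* predicates ``[@attr]``, ``[@attr = 'v']``, ``[../CHILD = 'v']``

Results are element string-values (concatenated descendant text) in
document order.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

_PRED_RE = re.compile(r"^(?P<name>[^\[\]]+)(?:\[(?P<pred>[^\]]+)\])?$")


def _split_steps(path: str) -> list[str]:
    """Split on '/' at bracket depth zero (predicates may contain '/')."""
    steps, buf, depth = [], [], 0
    for ch in path:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        if ch == "/" and depth == 0:
            steps.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    steps.append("".join(buf))
    return steps


def _strip_ns(tag: str) -> str:
    return tag.split("}", 1)[1] if "}" in tag else tag


def _pred_holds(node: ET.Element, pred: str,
                parents: dict[ET.Element, ET.Element]) -> bool:
    pred = pred.strip()
    if pred.startswith("@"):
        if "=" in pred:
            attr, _, value = pred.partition("=")
            attr = attr.strip().lstrip("@")
            value = value.strip().strip("'\"")
            return any(
                _strip_ns(k) == attr and v == value for k, v in node.attrib.items()
            )
        attr = pred.lstrip("@").strip()
        return any(_strip_ns(k) == attr for k in node.attrib)
    if pred.startswith("../"):
        rest = pred[3:]
        child_name, _, value = rest.partition("=")
        child_name = child_name.strip()
        value = value.strip().strip("'\"")
        parent = parents.get(node)
        if parent is None:
            return False
        return any(
            _strip_ns(c.tag) == child_name and (c.text or "").strip() == value
            for c in parent
        )
    raise NotImplementedError(f"oracle does not support predicate {pred!r}")


def _matches(node: ET.Element, step: str,
             parents: dict[ET.Element, ET.Element]) -> bool:
    m = _PRED_RE.match(step)
    if m is None:
        raise NotImplementedError(f"oracle does not support step {step!r}")
    if _strip_ns(node.tag) != m.group("name"):
        return False
    pred = m.group("pred")
    return pred is None or _pred_holds(node, pred, parents)


def _doc_order(root: ET.Element) -> list[ET.Element]:
    order = [root]
    for child in root:
        order.extend(_doc_order(child))
    return order


def oracle_eval(root: ET.Element, expression: str) -> list[str]:
    """Evaluate *expression* against *root*, returning string-values."""
    parents = {child: parent for parent in root.iter() for child in parent}
    if expression.startswith("//"):
        steps = _split_steps(expression[2:])
        nodes = [n for n in _doc_order(root) if _matches(n, steps[0], parents)]
    else:
        steps = _split_steps(expression)
        nodes = [c for c in root if _matches(c, steps[0], parents)]
    for step in steps[1:]:
        nodes = [c for n in nodes for c in n if _matches(c, step, parents)]
    return ["".join(n.itertext()) for n in nodes]


def oracle_extract(xml_text: str, expression: str) -> list[str]:
    return oracle_eval(ET.fromstring(xml_text), expression)
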