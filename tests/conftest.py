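import pytest
from hypothesis import HealthCheck, settings

from ontorules.data_model import AttributeSpec, Condition, Dataset, Example
from ontorules.hierarchy import EdgeList, sanitize

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def chain_hierarchy():
    """R -> A -> s and R -> B -> v: two leaf values under distinct parents."""
    return sanitize(EdgeList(pairs=[("R", "A"), ("A", "s"), ("R", "B"), ("B", "v")]))


@pytest.fixture
def diamond_hierarchy():
    """R -> X -> Z and R -> Y -> Z: a multi-parent leaf."""
    return sanitize(EdgeList(pairs=[("R", "X"), ("X", "Z"), ("R", "Y"), ("Y", "Z")]))


def make_dataset(rows, attrs=None, classes=("neg", "pos")):
    """Build a dataset from (id, values-dict, label) rows; attribute domains
    are inferred from the observed values unless given explicitly."""
    names = []
    for _, values, _ in rows:
        for k in values:
            if k not in names:
                names.append(k)
    schema = []
    for name in names:
        if attrs and name in attrs:
            schema.append(attrs[name])
        else:
            domain = []
            for _, values, _ in rows:
                v = values.get(name)
                if v is not None and v not in domain:
                    domain.append(v)
            schema.append(AttributeSpec(name=name, kind="nominal", domain=domain))
    schema.append(AttributeSpec(name="cls", kind="output", domain=classes))
    examples = [Example(id=i, values=dict(v), label=c) for i, v, c in rows]
    return Dataset(schema=schema, examples=examples)


@pytest.fixture
def color_dataset():
    """12 examples over two nominal attributes with a known concept."""
    rows = []
    i = 0
    for color in ("red", "red", "blue", "green"):
        for shape in ("circle", "square", "star"):
            label = "pos" if (color == "red" and shape != "star") else "neg"
            rows.append((f"e{i}", {"color": color, "shape": shape}, label))
            i += 1
    return make_dataset(rows)
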