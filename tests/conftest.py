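import numpy as np
import pytest

from scafslicer import (
    PatternMap,
    PorePattern,
    PrinterConfig,
    label_linear_gradient,
    make_fixture,
    rasterize,
    slice_volume,
)


@pytest.fixture(scope="session")
def printer():
    return PrinterConfig()


@pytest.fixture(scope="session")
def scaffold_factory(printer):
    """Cached builder of sliced-and-rasterized scaffold models.

    ``factory(patterns, size, pitch)`` slices a box of ``size`` mm (split
    into len(patterns) equal slabs along x when more than one pattern is
    given) and rasterizes the toolpaths at ``pitch``; returns
    (volume, layers, model).
    """
    cache = {}

    def factory(patterns, size=(20.0, 20.0, 10.0), pitch=0.1, support=True):
        key = (tuple(patterns), tuple(size), pitch, support)
        if key not in cache:
            volume = make_fixture("box", size, pitch)
            if len(patterns) > 1:
                volume = label_linear_gradient(volume, "x", len(patterns))
            pattern_map = PatternMap(
                {i + 1: PorePattern(p, k) for i, (p, k) in enumerate(patterns)}
            )
            layers = slice_volume(volume, pattern_map, printer, support=support)
            model = rasterize(layers, pitch, volume=volume)
            cache[key] = (volume, layers, model)
        return cache[key]

    return factory
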