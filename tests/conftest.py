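import numpy as np
import pytest

from oair import KernelSpec, Volume, generate_phantom

ALL_KERNELS = [
    "nearest", "trilinear", "lagrange4", "lagrange6", "lagrange8",
    "bspline3", "bspline4", "windowed_sinc",
]

#: kernels that reproduce grid values exactly at integer sample points
INTERPOLATING_KERNELS = [
    "nearest", "trilinear", "lagrange4", "lagrange6", "lagrange8", "windowed_sinc",
]

#: kernels whose footprint weights sum to exactly 1 at any offset
PARTITION_OF_UNITY_KERNELS = [
    "trilinear", "lagrange4", "lagrange6", "lagrange8", "bspline3", "bspline4",
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_random_volume():
    r = np.random.default_rng(42)
    return Volume(r.uniform(0.0, 100.0, (5, 5, 5)))


@pytest.fixture(scope="session")
def phantom32():
    return generate_phantom((32, 32, 32), (1.0, 1.0, 1.0), seed=3)


@pytest.fixture(scope="session")
def phantom48():
    return generate_phantom((48, 48, 48), (1.0, 1.0, 1.3), seed=5)


def naive_sample(data, point, spec: KernelSpec):
    """Independent oracle: literal triple-loop separable sum over the
    whole grid with boundary handling by index mapping."""
    from oair.kernels import kernel_value

    n0, n1, n2 = data.shape
    x, y, z = point

    def bmap(i, n):
        if 0 <= i < n:
            return i
        if spec.boundary == "zero":
            return None
        if spec.boundary == "clamp":
            return min(max(i, 0), n - 1)
        while i < 0 or i >= n:
            if i < 0:
                i = -i
            if i >= n:
                i = 2 * n - 2 - i
        return i

    r = spec.support_radius
    acc = 0.0
    import math

    hw = int(math.ceil(r))
    for X in range(int(math.floor(x)) - hw, int(math.floor(x)) + hw + 2):
        wx = kernel_value(spec, x - X)
        if wx == 0.0:
            continue
        iX = bmap(X, n0)
        for Y in range(int(math.floor(y)) - hw, int(math.floor(y)) + hw + 2):
            wy = kernel_value(spec, y - Y)
            if wy == 0.0:
                continue
            iY = bmap(Y, n1)
            for Z in range(int(math.floor(z)) - hw, int(math.floor(z)) + hw + 2):
                wz = kernel_value(spec, z - Z)
                if wz == 0.0:
                    continue
                iZ = bmap(Z, n2)
                if iX is None or iY is None or iZ is None:
                    continue
                acc += wx * wy * wz * data[iX, iY, iZ]
    return acc
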