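"""Blob enhancement with a negative Laplacian-of-Gaussian kernel.

A bouton appears as a bright, roughly Gaussian blob riding on an axon.
Convolving the projection with the *negative* LoG kernel turns each
bright blob of radius ``r`` into a local maximum, with the response
peaking when the kernel scale satisfies ``sigma = r / sqrt(2)``.
Structures much smaller than sigma (shot noise, thin speckle) are
suppressed, which both stabilizes the downstream interest-point detector
and speeds it up by thinning false candidates.

The LoG kernel used here is::

    LoG(x, y; s) = (x^2 + y^2 - 2 s^2) / (2 pi s^5) * exp(-(x^2+y^2) / (2 s^2))

Note the s^5 normalization of this formulation (the classical kernel
divides by s^6); with it the centre value at scale s is -1/(pi s^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_io import Image2D


@dataclass
class EnhancementConfig:
    """Scale and discretization of the LoG enhancement stage.

    sigma
        Kernel scale in pixels.  Default 4, the working bouton scale for
        0.147 µm/px two-photon data (mean measured bouton sd ≈ 4.56 px).
    support_halfwidth
        Kernel half-extent h; the kernel is (2h+1)² and must cover at
        least 3·sigma.  ``None`` means ceil(3·sigma).
    zero_mean
        Subtract the discrete mean so the truncated kernel sums to zero
        and flat background maps exactly to 0.
    nms_intensity_source
        Which image the NMS stage reads intensities from:
        ``"enhanced"`` (default) or ``"projection"``.
    """

    sigma: float = 4.0
    support_halfwidth: int | None = None
    zero_mean: bool = True
    nms_intensity_source: str = "enhanced"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        min_h = math.ceil(3 * self.sigma)
        if self.support_halfwidth is None:
            self.support_halfwidth = min_h
        elif self.support_halfwidth < min_h:
            raise ValueError(
                f"support_halfwidth {self.support_halfwidth} < ceil(3*sigma) = {min_h}"
            )
        if self.nms_intensity_source not in ("enhanced", "projection"):
            raise ValueError(f"unknown intensity source {self.nms_intensity_source!r}")


@dataclass
class Kernel2D:
    """Square convolution kernel of odd side, centred at the origin."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n or n % 2 == 0:
            raise ValueError("kernel must be square with odd side length")


def log_kernel(config: EnhancementConfig) -> Kernel2D:
    """Sample the LoG kernel on the integer grid [-h, h]^2.

    With ``zero_mean`` the discrete mean is subtracted so the weights sum
    to zero (within 1e-12); the continuous kernel integrates to zero but
    its truncation does not.
    """
    h = config.support_halfwidth
    s = config.sigma
    y, x = np.mgrid[-h : h + 1, -h : h + 1].astype(np.float64)
    r2 = x * x + y * y
    w = (r2 - 2 * s * s) / (2 * np.pi * s**5) * np.exp(-r2 / (2 * s * s))
    if config.zero_mean:
        w = w - w.mean()
    return Kernel2D(w)


def optimal_sigma_for_radius(r: float) -> float:
    """Scale maximizing the -LoG centre response to a blob of radius r.

    Setting the derivative of the integrated response to zero gives
    ``r^2 - 2 sigma^2 = 0``, i.e. ``sigma = r / sqrt(2)``.
    """
    if r <= 0:
        raise ValueError("blob radius must be positive")
    return r / math.sqrt(2.0)


def enhance(image: Image2D, config: EnhancementConfig | None = None) -> Image2D:
    """Convolve with the negative LoG kernel (bright-blob enhancer).

    Output has the input's shape; borders use reflective padding.
    """
    if config is None:
        config = EnhancementConfig()
    kernel = log_kernel(config)
    n = kernel.weights.shape[0]
    if min(image.shape) < n:
        raise ValueError(
            f"image {image.shape} smaller than kernel support {n}x{n}"
        )
    out = ndimage.convolve(image.pixels, -kernel.weights, mode="mirror")
    return Image2D(out)


def scale_normalized_blob_response(radius: float, sigma: float) -> float:
    """Scale-normalized centre response of -LoG to a bright disc.

    Renders a disc of the given radius, enhances it at ``sigma``, and
    returns sigma times the centre value.  The sigma factor is the
    scale normalization needed to compare responses across scales with
    this kernel's 1/sigma^5 amplitude (the classical sigma^2-normalized
    Laplacian divided by the kernel's extra 1/sigma); with it the
    response over sigma peaks at ``radius / sqrt(2)``, the blob-matching
    rule :func:`optimal_sigma_for_radius` encodes.
    """
    side = 2 * int(math.ceil(radius + 4 * sigma)) + 1
    centre = side // 2
    y, x = np.mgrid[0:side, 0:side].astype(np.float64)
    disc = ((y - centre) ** 2 + (x - centre) ** 2 <= radius**2).astype(np.float64)
    out = enhance(Image2D(disc), EnhancementConfig(sigma=sigma))
    return float(sigma * out.pixels[centre, centre])
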