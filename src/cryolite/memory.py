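"""Memory footprint estimate for refinement jobs.

Resolving detail at the Nyquist frequency requires a two-fold oversampled
Fourier grid per class, i.e. ``(2 D)^3`` values of 4 bytes each in single
precision; accommodating the reconstructed object alongside multiplies the
practical footprint by roughly 2.5.  The total scales linearly with the
number of classes.
"""

from __future__ import annotations

__all__ = ["estimate_memory"]


def estimate_memory(image_size: int, n_classes: int, pad: int = 2,
                    bytes_per_value: int = 4) -> dict:
    """Bytes needed per class and in total for a refinement job.

    Returns a dict with ``per_class_bytes`` (the oversampled grid) and
    ``total_bytes`` (2.5 x per-class x classes).
    """
    if image_size < 0 or image_size % 2:
        raise ValueError("image size must be a non-negative even integer")
    if n_classes < 1:
        raise ValueError("need at least one class")
    per_class = (pad * image_size) ** 3 * bytes_per_value
    total = 2.5 * per_class * n_classes
    return {"per_class_bytes": per_class, "total_bytes": total,
            "grid_size": pad * image_size}
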