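"""Minimal estimator base providing the get_params/set_params protocol.

The classes in this package follow the scikit-learn estimator contract
(constructor stores hyper-parameters verbatim; fitted state lives in
trailing-underscore attributes) so they compose with sklearn pipelines and
`clone`, without making scikit-learn itself a runtime dependency.
"""

from __future__ import annotations

import inspect
from typing import Any


class BaseEstimator:
    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params: Any) -> "BaseEstimator":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for estimator {type(self).__name__}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    def _check_is_fitted(self, attr: str) -> None:
        if not hasattr(self, attr):
            raise AttributeError(
                f"This {type(self).__name__} instance is not fitted yet; "
                "call 'fit' before using this method."
            )
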