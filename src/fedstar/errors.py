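"""Exception hierarchy shared across the runtime."""


class FedstarError(Exception):
    """Base class for all runtime errors."""


class PlanParseError(FedstarError):
    """The plan document is not well-formed in the plan dialect."""


class PlanValidationError(FedstarError):
    """A structurally complete plan violates one or more invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class IntegrityError(FedstarError):
    """A binary frame or archive failed an integrity check."""


class ProtocolError(FedstarError):
    """An envelope could not be decoded or carries an unknown kind."""


class AuthorizationError(FedstarError):
    """A peer outside the plan roster attempted a protocol action."""


class AggregationError(FedstarError):
    """An aggregation group was empty, mismatched, or the method misbehaved."""


class FederationHalt(FedstarError):
    """Round cutoff reached with fewer submissions than the quorum allows."""

    def __init__(self, round_num, received, quorum):
        self.round_num = round_num
        self.received = received
        self.quorum = quorum
        super().__init__(
            f"round {round_num} halted: {received} submissions < quorum {quorum}"
        )


class TaskError(FedstarError):
    """A local task failed on a collaborator."""


class DivergenceError(FedstarError):
    """Training produced a non-finite loss (learning rate too large)."""
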