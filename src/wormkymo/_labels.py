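"""Behavioral state labels shared across the simulator and the analysis stages."""

FORWARD = "FORWARD"
BACKWARD = "BACKWARD"
OMEGA = "OMEGA"
UNKNOWN = "UNKNOWN"

STATE_LABELS = (FORWARD, BACKWARD, OMEGA, UNKNOWN)
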