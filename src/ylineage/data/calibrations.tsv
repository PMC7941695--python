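# Built-in calibration bounds (kyr) for Y-DNA main-trunk haplogroups.
# Configuration data for dating-input generation, not asserted as scientific
# truth; user-supplied calibrations override these.
haplogroup	lower_kyr	upper_kyr
Y-Adam	200	300
A1	130	180
BT	80	130
CT	65	90
DE	60	80
CF	60	80
F	45	60
K	40	55
NO	35	45
P	30	45
R	25	35
O	25	35
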