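# Oral reference doses (RfD, mg/kg-day) and inhalation reference
# concentrations (RfC, mg/m3) for the ten priority-pollutant metals.
# Sources: IRIS (US EPA Integrated Risk Information System), ATSDR,
# HEAST, Oak Ridge National Laboratory, California EPA.
Ag: {rfd: 5.0e-3, source_rfd: IRIS}
Cd: {rfd: 1.0e-3, rfc: 1.0e-5, source_rfd: IRIS, source_rfc: ATSDR}
Cr: {rfd: 1.5, source_rfd: IRIS}
Cu: {rfd: 4.0e-2, source_rfd: HEAST}
Ni: {rfd: 2.0e-2, rfc: 9.0e-5, source_rfd: IRIS, source_rfc: ATSDR}
Pb: {rfd: 1.4e-4, source_rfd: Oak Ridge}
Se: {rfd: 5.0e-3, rfc: 2.0e-2, source_rfd: IRIS, source_rfc: Cal EPA}
Tl: {rfd: 3.0e-6, source_rfd: IRIS}
Zn: {rfd: 3.0e-1, source_rfd: IRIS}
Hg: {rfd: 1.6e-4, rfc: 3.0e-4, source_rfd: Cal EPA, source_rfc: IRIS}
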