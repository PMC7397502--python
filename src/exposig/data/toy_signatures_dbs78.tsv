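Type	background	exposure
AC>CA	0	0
AC>CG	0	0
AC>CT	0	0
AC>GA	0	0
AC>GG	0	0
AC>GT	0	0
AC>TA	0	0
AC>TG	0	0
AC>TT	0	0
AT>CA	0.1	0
AT>CC	0	0
AT>CG	0	0
AT>GA	0	0
AT>GC	0	0
AT>TA	0	0
CC>AA	0	0.7
CC>AG	0	0
CC>AT	0	0.05
CC>GA	0	0
CC>GG	0	0
CC>GT	0	0
CC>TA	0	0.05
CC>TG	0	0
CC>TT	0.4	0
CG>AA	0	0
CG>AC	0	0
CG>AT	0	0
CG>GA	0	0
CG>GC	0	0
CG>TA	0	0
CT>AA	0	0
CT>AC	0	0
CT>AG	0	0
CT>GA	0	0
CT>GC	0	0
CT>GG	0	0
CT>TA	0	0
CT>TC	0	0
CT>TG	0	0
GC>AA	0.1	0
GC>AG	0	0
GC>AT	0	0
GC>CA	0	0
GC>CG	0	0
GC>TA	0	0
TA>AC	0	0
TA>AG	0	0
TA>AT	0	0
TA>CC	0	0
TA>CG	0	0
TA>GC	0	0
TC>AA	0	0
TC>AG	0	0
TC>AT	0	0
TC>CA	0	0
TC>CG	0	0
TC>CT	0.2	0
TC>GA	0	0
TC>GG	0	0
TC>GT	0	0
TG>AA	0	0
TG>AC	0	0
TG>AT	0	0.1
TG>CA	0	0.1
TG>CC	0	0
TG>CT	0	0
TG>GA	0	0
TG>GC	0	0
TG>GT	0	0
TT>AA	0	0
TT>AC	0	0
TT>AG	0	0
TT>CA	0	0
TT>CC	0.2	0
TT>CG	0	0
TT>GA	0	0
TT>GC	0	0
TT>GG	0	0
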