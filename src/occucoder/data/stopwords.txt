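# Default English stop-word list for job-title preprocessing.
# One token per line; lines starting with "#" are ignored.
a
an
and
as
at
by
for
from
in
into
is
it
n.e.c
nec
of
on
or
other
per
the
to
with
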