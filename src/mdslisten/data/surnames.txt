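Smith
Johnson
Williams
Brown
Jones
Miller
Davis
Garcia
Rodriguez
Wilson
Martinez
Anderson
Taylor
Moore
Jackson
Martin
Thompson
White
Harris
Clark
Lewis
Walker
Hall
Young
King
Allen
Scott
Green
Baker
Adams
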