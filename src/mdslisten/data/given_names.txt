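Jane
John
Mary
Robert
Linda
Michael
Susan
David
Karen
James
Patricia
Richard
Barbara
Nancy
Charles
Carol
Daniel
Ruth
Mark
Sarah
Paul
Laura
Steven
Emily
George
Helen
Frank
Alice
Dana
Emma
Brian
Joan
Holly
Barry
Donna
Becky
Joseph
Maria
Ryan
Gloria
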