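# Biotea-vocabulary -> SIO mapping profile (key=value; CURIEs resolved
# against the package namespace registry).  Sections: class., objprop.,
# dataprop. ; a datatype rule value is "objprop;class;prefix".

# -- classes --------------------------------------------------------------
class.bibo:AcademicArticle=sio:peer-reviewed-article
class.bibo:Document=sio:document
class.bibo:Book=sio:book
class.bibo:Journal=sio:journal
class.foaf:Person=sio:person
class.foaf:Organization=sio:organization
class.doco:Section=sio:document-section
class.doco:Paragraph=sio:paragraph

# -- object properties ----------------------------------------------------
objprop.bibo:cites=sio:cites
objprop.bibo:citedBy=sio:is-cited-by
objprop.dcterms:hasPart=sio:has-part
objprop.dcterms:isPartOf=sio:is-part-of
objprop.ao:annotatesResource=sio:is-data-item-in

# -- datatype rules: objprop;class;prefix ---------------------------------
dataprop.bibo:pmid=sio:has-identifier;sio:identifier;pmid:
dataprop.bibo:doi=sio:has-identifier;sio:identifier;doi:
dataprop.bibo:identifier=sio:has-attribute;sio:record-identifier;pmc:
dataprop.dcterms:title=sio:has-attribute;sio:title;
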