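# Hamburg 2019 calendar definition: school breaks, legal holidays and major
# public events affecting non-time-critical ambulance demand. Dates are the
# public Hamburg 2019 dates; ranges are inclusive.
year: 2019
breaks:
  - name: half-term / ski break
    start: 2019-02-01
    end: 2019-02-01
  - name: spring (ski) break
    start: 2019-03-04
    end: 2019-03-15
  - name: Pentecost break
    start: 2019-05-13
    end: 2019-05-17
  - name: summer break
    start: 2019-06-27
    end: 2019-08-07
  - name: autumn break
    start: 2019-10-04
    end: 2019-10-18
  - name: Christmas break
    start: 2019-12-23
    end: 2019-12-31
holidays:
  - name: New Year
    start: 2019-01-01
    end: 2019-01-01
  - name: Good Friday
    start: 2019-04-19
    end: 2019-04-19
  - name: Easter Monday
    start: 2019-04-22
    end: 2019-04-22
  - name: Labor Day
    start: 2019-05-01
    end: 2019-05-01
  - name: Ascension Day
    start: 2019-05-30
    end: 2019-05-30
  - name: Whit Monday
    start: 2019-06-10
    end: 2019-06-10
  - name: German Unity Day
    start: 2019-10-03
    end: 2019-10-03
  - name: Reformation Day
    start: 2019-10-31
    end: 2019-10-31
  - name: Christmas Day
    start: 2019-12-25
    end: 2019-12-25
  - name: Boxing Day
    start: 2019-12-26
    end: 2019-12-26
events:
  - name: spring DOM fair
    start: 2019-03-22
    end: 2019-04-22
  - name: Harbour Birthday
    start: 2019-05-10
    end: 2019-05-12
  - name: Harley Days
    start: 2019-06-21
    end: 2019-06-23
  - name: Schlagermove
    start: 2019-07-12
    end: 2019-07-13
  - name: summer DOM fair
    start: 2019-07-26
    end: 2019-08-25
  - name: Christopher Street Day
    start: 2019-08-02
    end: 2019-08-04
  - name: winter DOM fair
    start: 2019-11-08
    end: 2019-12-08
  - name: Christmas market season
    start: 2019-11-25
    end: 2019-12-23
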